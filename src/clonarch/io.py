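"""Readers and writers for the pipeline's interchange formats.

Everything travels as plain text: tab-separated tables for pileups,
amplicon measurements, colonies, truth labels and cohort matrices;
FASTA for germline V segments; VCF 4.2 for screened variant candidates.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Union

import pandas as pd

from .cohort import CaseRecord, Subtype
from .compartments import LineageCall
from .igh import ClonalityResult, ColonySequence
from .screen import Effect, PileupSite, VariantCandidate
from .simulate import AmpliconMeasurement, TruthLineage

PathLike = Union[str, Path]

PILEUP_COLUMNS = [
    "sample", "contig", "pos", "ref", "alt",
    "alt_fwd", "alt_rev", "depth_fwd", "depth_rev", "effect", "known_snp",
]
AMPLICON_COLUMNS = ["sample", "mutation_id", "compartment", "alt_count", "depth"]
COLONY_COLUMNS = [
    "sample", "colony_id", "v_gene", "d_gene", "j_gene",
    "junction_aa", "v_sequence",
]


def write_pileup_tsv(sites: Sequence[PileupSite], path: PathLike) -> None:
    rows = [
        {
            "sample": s.sample, "contig": s.contig, "pos": s.pos,
            "ref": s.ref, "alt": s.alt, "alt_fwd": s.alt_fwd,
            "alt_rev": s.alt_rev, "depth_fwd": s.depth_fwd,
            "depth_rev": s.depth_rev, "effect": s.effect.value,
            "known_snp": s.known_snp,
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=PILEUP_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pileup_tsv(path: PathLike) -> List[PileupSite]:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "contig": str})
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pileup TSV missing columns: {sorted(missing)}")
    return [
        PileupSite(
            sample=row["sample"], contig=row["contig"], pos=int(row["pos"]),
            ref=row["ref"], alt=row["alt"],
            alt_fwd=int(row["alt_fwd"]), alt_rev=int(row["alt_rev"]),
            depth_fwd=int(row["depth_fwd"]), depth_rev=int(row["depth_rev"]),
            effect=Effect(row["effect"]),
            known_snp=bool(row["known_snp"]) if not isinstance(row["known_snp"], str)
            else row["known_snp"].strip().lower() in {"true", "1", "yes"},
        )
        for _, row in df.iterrows()
    ]


def write_amplicon_tsv(
    measurements: Sequence[AmpliconMeasurement], path: PathLike
) -> None:
    rows = [
        {
            "sample": m.sample, "mutation_id": m.mutation_id,
            "compartment": m.compartment, "alt_count": m.alt_count,
            "depth": m.depth,
        }
        for m in measurements
    ]
    pd.DataFrame(rows, columns=AMPLICON_COLUMNS).to_csv(path, sep="\t", index=False)


def read_amplicon_tsv(path: PathLike) -> List[AmpliconMeasurement]:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "mutation_id": str})
    return [
        AmpliconMeasurement(
            sample=row["sample"], mutation_id=row["mutation_id"],
            compartment=row["compartment"], alt_count=int(row["alt_count"]),
            depth=int(row["depth"]),
        )
        for _, row in df.iterrows()
    ]


def write_colony_tsv(colonies: Sequence[ColonySequence], path: PathLike) -> None:
    rows = [
        {
            "sample": c.sample, "colony_id": c.colony_id, "v_gene": c.v_gene,
            "d_gene": c.d_gene if c.d_gene is not None else "",
            "j_gene": c.j_gene, "junction_aa": c.junction_aa,
            "v_sequence": c.v_sequence,
        }
        for c in colonies
    ]
    pd.DataFrame(rows, columns=COLONY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_colony_tsv(path: PathLike) -> List[ColonySequence]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        ColonySequence(
            sample=row["sample"], colony_id=row["colony_id"],
            v_gene=row["v_gene"],
            d_gene=row["d_gene"] if row["d_gene"] else None,
            j_gene=row["j_gene"], junction_aa=row["junction_aa"],
            v_sequence=row["v_sequence"],
        )
        for _, row in df.iterrows()
    ]


def write_truth_tsv(truth: Mapping[str, TruthLineage], path: PathLike) -> None:
    df = pd.DataFrame(
        [{"mutation_id": k, "truth_lineage": v.value} for k, v in sorted(truth.items())]
    )
    df.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: PathLike) -> Dict[str, TruthLineage]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {
        row["mutation_id"]: TruthLineage(row["truth_lineage"])
        for _, row in df.iterrows()
    }


def write_gene_map_tsv(gene_map: Mapping[str, str], path: PathLike) -> None:
    df = pd.DataFrame(
        [{"mutation_id": k, "gene": v} for k, v in sorted(gene_map.items())]
    )
    df.to_csv(path, sep="\t", index=False)


def read_gene_map_tsv(path: PathLike) -> Dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {row["mutation_id"]: row["gene"] for _, row in df.iterrows()}


def write_calls_tsv(calls: Sequence[LineageCall], path: PathLike) -> None:
    rows = [
        {
            "mutation_id": c.mutation_id, "call": c.call.value,
            "detected_pd1": c.detected_pd1, "detected_cd20": c.detected_cd20,
            "enrichment_ratio": c.enrichment_ratio, "enriched": c.enriched,
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_clonality_tsv(
    results: Sequence[ClonalityResult], path: PathLike
) -> None:
    rows = []
    for r in results:
        if not r.clones:
            rows.append(
                {"sample": r.sample, "call": r.call.value, "clone": "",
                 "size": "", "identity": "", "mutation_status": ""}
            )
        for clone, ident, status in zip(r.clones, r.identities, r.mutation_status):
            v, d, j, junction = clone.vdj_key
            rows.append(
                {
                    "sample": r.sample, "call": r.call.value,
                    "clone": f"{v}/{d or '-'}/{j} {junction}",
                    "size": clone.size, "identity": ident,
                    "mutation_status": status.value,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_case_matrix_tsv(cases: Sequence[CaseRecord], path: PathLike) -> None:
    """Long-format per-case mutation matrix (one row per case-gene pair)."""
    rows = []
    for case in cases:
        for gene in sorted(case.mutated_genes):
            rows.append(
                {
                    "case_id": case.case_id, "subtype": case.subtype.value,
                    "microdissected": case.microdissected, "gene": gene,
                    "mutated": True,
                }
            )
        if not case.mutated_genes:
            rows.append(
                {
                    "case_id": case.case_id, "subtype": case.subtype.value,
                    "microdissected": case.microdissected, "gene": "",
                    "mutated": False,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_case_matrix_tsv(path: PathLike) -> List[CaseRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"case_id": str}, keep_default_na=False)
    cases: List[CaseRecord] = []
    for (case_id, subtype, lmd), group in df.groupby(
        ["case_id", "subtype", "microdissected"], sort=False
    ):
        genes = frozenset(
            g for g, m in zip(group["gene"], group["mutated"])
            if g and (m is True or str(m).strip().lower() in {"true", "1", "yes"})
        )
        try:
            st = Subtype(subtype)
        except ValueError as exc:
            raise ValueError(f"unknown subtype label {subtype!r}") from exc
        cases.append(
            CaseRecord(
                case_id=case_id, subtype=st, mutated_genes=genes,
                microdissected=bool(lmd) if not isinstance(lmd, str)
                else lmd.strip().lower() in {"true", "1", "yes"},
            )
        )
    return cases


def write_candidates_vcf(
    candidates: Sequence[VariantCandidate], path: PathLike
) -> None:
    """Screened candidates as VCF 4.2 with the screening verdict in INFO."""
    contigs = sorted({c.site.contig for c in candidates})
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">',
        '##INFO=<ID=ALTF,Number=1,Type=Integer,Description="Forward-strand alt reads">',
        '##INFO=<ID=ALTR,Number=1,Type=Integer,Description="Reverse-strand alt reads">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
        '##INFO=<ID=REASON,Number=1,Type=String,Description="First failed screening rule">',
        '##FILTER=<ID=screen,Description="Removed by the somatic screening cascade">',
    ]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for cand in candidates:
        s = cand.site
        info = (
            f"VAF={cand.vaf:.6g};ALTF={s.alt_fwd};ALTR={s.alt_rev};DP={s.depth_total}"
        )
        if cand.removal_reason is not None:
            info += f";REASON={cand.removal_reason.value}"
        filt = "PASS" if cand.retained else "screen"
        lines.append(
            f"{s.contig}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\t{filt}\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
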