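"""End-to-end orchestration: simulate -> screen -> assign -> igh -> summarize.

Runs each analysis stage on a simulated cohort (or user-supplied
inputs through the CLI's stage commands), writing every intermediate
as plain text plus a JSON manifest with a SHA-256 digest per file, so
that a rerun under the same configuration and seed is verifiably
identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
from pydantic import BaseModel, Field

from . import io
from .cohort import CaseRecord, Subtype, build_table
from .compartments import DetectionThresholds, LineageCall, classify_lineage
from .igh import call_clonality, load_germline_v_references
from .screen import ScreenThresholds, screen_variants
from .simulate import SimulationConfig, build_default_architecture, simulate_amplicons, simulate_igh_colonies, simulate_pileup

__all__ = ["IghConfig", "PipelineConfig", "run_pipeline"]


class IghConfig(BaseModel):
    n_colonies: int = Field(default=12, ge=1)
    clone_fractions: List[float] = Field(default_factory=lambda: [2 / 12])
    target_identity: float = Field(default=72.0, gt=0.0, le=100.0)
    min_clone_size: int = Field(default=2, ge=2)
    germline_fasta: Optional[str] = None


class PipelineConfig(BaseModel):
    """Per-stage configuration; the seed governs every stage."""

    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    detection: Dict[str, float] = Field(
        default_factory=lambda: {"min_vaf": 0.02, "min_alt": 5, "min_depth": 100}
    )
    enrichment_factor: float = Field(default=1.5, gt=0.0)
    igh: IghConfig = Field(default_factory=IghConfig)
    seed: int = 0
    log_level: str = "INFO"

    def detection_thresholds(self) -> DetectionThresholds:
        return DetectionThresholds(
            min_vaf=float(self.detection["min_vaf"]),
            min_alt=int(self.detection["min_alt"]),
            min_depth=int(self.detection["min_depth"]),
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> Dict[str, str]:
    """Run every stage on a simulated cohort; return {file: digest}.

    Fails fast on configuration problems (e.g. a missing germline
    FASTA) before any stage output is written.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if config.igh.germline_fasta is not None:
        fasta = Path(config.igh.germline_fasta)
        if not fasta.exists():
            raise FileNotFoundError(
                f"germline FASTA not found: {config.igh.germline_fasta}"
            )
        germline = load_germline_v_references(fasta)
    else:
        germline = load_germline_v_references()

    sim = config.simulation.model_copy(update={"seed": config.seed})
    rng = np.random.default_rng(config.seed)
    tree = build_default_architecture(sim)
    thresholds = config.detection_thresholds()

    # stage 1: simulate
    pileups, amplicons = [], []
    case_ids = [f"sim{i + 1:03d}" for i in range(sim.n_cases)]
    for case_id in case_ids:
        pileups.extend(simulate_pileup(tree, sim, sample=case_id, rng=rng))
        amplicons.extend(simulate_amplicons(tree, sim, sample=case_id, rng=rng))
    truth = {m.id: m.truth_lineage for m in tree.mutations.values()}
    gene_map = {m.id: m.gene for m in tree.mutations.values()}
    io.write_pileup_tsv(pileups, out / "pileup.tsv")
    io.write_amplicon_tsv(amplicons, out / "amplicons.tsv")
    io.write_truth_tsv(truth, out / "truth.tsv")
    io.write_gene_map_tsv(gene_map, out / "gene_map.tsv")

    # stage 2: screen
    candidates = screen_variants(pileups, ScreenThresholds())
    io.write_candidates_vcf(candidates, out / "candidates.vcf")

    # stage 3: assign lineages per case from amplicon measurements
    calls: List[LineageCall] = []
    case_genes: Dict[str, set] = {c: set() for c in case_ids}
    for case_id in case_ids:
        per_case = [m for m in amplicons if m.sample == case_id]
        for mut_id in sorted({m.mutation_id for m in per_case}):
            call = classify_lineage(
                [m for m in per_case if m.mutation_id == mut_id],
                thresholds,
                config.enrichment_factor,
            )
            calls.append(call)
            if call.call.value in {"multilineal", "T_specific", "B_specific"}:
                case_genes[case_id].add(gene_map[mut_id])
    io.write_calls_tsv(calls, out / "lineage_calls.tsv")

    # stage 4: IgH clonality per case
    results = []
    for case_id in case_ids:
        colonies = simulate_igh_colonies(
            n_colonies=config.igh.n_colonies,
            clone_fractions=config.igh.clone_fractions,
            target_identity=config.igh.target_identity,
            seed=int(rng.integers(2**31)),
            sample=case_id,
            germline_refs=germline,
        )
        results.append(
            call_clonality(
                colonies,
                min_clone_size=config.igh.min_clone_size,
                germline_refs=germline,
            )
        )
    io.write_clonality_tsv(results, out / "clonality.tsv")

    # stage 5: cohort summary over the simulated cases
    cases = [
        CaseRecord(
            case_id=case_id,
            subtype=Subtype.AITL,
            mutated_genes=frozenset(case_genes[case_id]),
            microdissected=True,
        )
        for case_id in case_ids
    ]
    genes = sorted({g for gs in case_genes.values() for g in gs}) or ["TET2"]
    table = build_table(cases, genes)
    table.to_dataframe().to_csv(out / "frequency_table.tsv", sep="\t")
    io.write_case_matrix_tsv(cases, out / "case_matrix.tsv")

    (out / "config.json").write_text(config.model_dump_json(indent=2) + "\n")
    files = sorted(p for p in out.iterdir() if p.name != "manifest.json")
    manifest = {p.name: _sha256(p) for p in files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
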