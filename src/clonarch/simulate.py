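"""Synthetic cohorts with a multistep, multilineal clonal architecture.

The generative model mirrors the clonal structure inferred for nodal
T-cell lymphomas with a T follicular helper phenotype: an ancestral
premalignant clone carrying epigenetic-regulator mutations (TET2,
DNMT3A) differentiates into both lineages; a T-lineage tumor subclone
acquires the hotspot mutations (G17V RHOA, IDH2); and, optionally, a
B-lineage subclone of infiltrating B cells acquires its own mutations
(NOTCH1-like).  Three assayed cell populations are emulated: the whole
tumor, laser-microdissected PD1+ cells (tumor enriched) and CD20+ B
cells (tumor depleted).

Read counts follow the simplest model consistent with deep amplicon
counting: Poisson total depth, binomial alt reads at the expected VAF
folded with a per-base substitution error, and a binomial strand split.
Sequencing error moves the alt probability to ``v' = v(1-e) + (1-v)e/3``
(substitutions hit the specific alt base a third of the time).

IgH colony simulation plants expanded B-cell clones — colonies sharing
one V/D/J rearrangement and junction — in a polyclonal background, with
V segments mutated away from a packaged germline reference to a target
percent identity, emulating somatic hypermutation.
"""

from __future__ import annotations

import string
import zlib
from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .igh import ColonySequence, load_germline_v_references
from .screen import Effect, PileupSite

__all__ = [
    "COMPARTMENTS",
    "Lineage",
    "TruthLineage",
    "Zygosity",
    "MutationSpec",
    "CloneNode",
    "CloneTree",
    "CompartmentMix",
    "SimulationConfig",
    "build_default_architecture",
    "expected_vaf",
    "simulate_pileup",
    "simulate_amplicons",
    "simulate_igh_colonies",
    "AmpliconMeasurement",
]

COMPARTMENTS = ("whole_tumor", "PD1pos", "CD20pos")


class Lineage(str, Enum):
    ancestral = "ancestral"
    T = "T"
    B = "B"


class TruthLineage(str, Enum):
    multilineal = "multilineal"
    T_specific = "T_specific"
    B_specific = "B_specific"


_LINEAGE_TO_TRUTH = {
    Lineage.ancestral: TruthLineage.multilineal,
    Lineage.T: TruthLineage.T_specific,
    Lineage.B: TruthLineage.B_specific,
}


class Zygosity(str, Enum):
    het = "het"
    hom = "hom"


@dataclass(frozen=True)
class MutationSpec:
    id: str
    gene: str
    effect: Effect
    zygosity: Zygosity
    truth_lineage: TruthLineage


@dataclass(frozen=True)
class CloneNode:
    id: str
    parent: Optional[str]
    lineage: Lineage
    mutations: tuple[str, ...]
    cell_fraction_by_compartment: Mapping[str, float]


@dataclass(frozen=True)
class CloneTree:
    """Clonal hierarchy with per-compartment cell fractions.

    The cell fraction of a node is the fraction of cells in a
    compartment carrying that node's mutations (nested subclones are
    included in their ancestors' fractions), so a child's fraction can
    never exceed its parent's and sibling subtrees sum to at most the
    parent within each compartment.
    """

    nodes: Mapping[str, CloneNode]
    mutations: Mapping[str, MutationSpec]

    def __post_init__(self) -> None:
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise ValueError("clone tree must have exactly one root")
        for node in self.nodes.values():
            for comp, frac in node.cell_fraction_by_compartment.items():
                if not 0.0 <= frac <= 1.0:
                    raise ValueError(
                        f"node {node.id}: fraction {frac} in {comp} not in [0,1]"
                    )
            if node.parent is not None:
                parent = self.nodes[node.parent]
                for comp, frac in node.cell_fraction_by_compartment.items():
                    if frac > parent.cell_fraction_by_compartment[comp] + 1e-12:
                        raise ValueError(
                            f"node {node.id} exceeds parent fraction in {comp}"
                        )
        # disjoint sibling subtrees must fit inside the parent
        for parent in self.nodes.values():
            children = [n for n in self.nodes.values() if n.parent == parent.id]
            for comp in parent.cell_fraction_by_compartment:
                total = sum(
                    c.cell_fraction_by_compartment.get(comp, 0.0)
                    for c in children
                )
                if total > parent.cell_fraction_by_compartment[comp] + 1e-12:
                    raise ValueError(
                        f"children of {parent.id} exceed its fraction in {comp}"
                    )

    def node_of_mutation(self, mutation_id: str) -> CloneNode:
        for node in self.nodes.values():
            if mutation_id in node.mutations:
                return node
        raise KeyError(f"mutation {mutation_id} not found in tree")

    def carrier_fraction(self, mutation_id: str, compartment: str) -> float:
        node = self.node_of_mutation(mutation_id)
        fractions = node.cell_fraction_by_compartment
        if compartment not in fractions:
            raise KeyError(f"unknown compartment {compartment!r}")
        return fractions[compartment]


class CompartmentMix(BaseModel):
    """Cell fractions of each clone within one assayed compartment."""

    ancestral: float = Field(ge=0.0, le=1.0)
    t_subclone: float = Field(ge=0.0, le=1.0)
    b_subclone: float = Field(ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _nested(self) -> "CompartmentMix":
        if self.t_subclone + self.b_subclone > self.ancestral + 1e-12:
            raise ValueError(
                "subclone fractions exceed the ancestral clone fraction"
            )
        return self


def _default_purities() -> Dict[str, CompartmentMix]:
    # PD1+ microdissection enriches the T-lineage tumor subclone,
    # CD20+ microdissection depletes it and enriches infiltrating B cells.
    return {
        "whole_tumor": CompartmentMix(ancestral=0.6, t_subclone=0.35, b_subclone=0.10),
        "PD1pos": CompartmentMix(ancestral=0.8, t_subclone=0.75, b_subclone=0.0),
        "CD20pos": CompartmentMix(ancestral=0.4, t_subclone=0.0, b_subclone=0.30),
    }


class SimulationConfig(BaseModel):
    """Study conditions for one simulated cohort.

    Depths are stage means: ``depth_mean`` for targeted capture
    sequencing, ``amplicon_depth_mean`` for amplicon validation.
    ``error_rate`` is the per-base substitution probability.
    """

    depth_mean: float = Field(default=200.0, ge=1.0)
    amplicon_depth_mean: float = Field(default=2000.0, ge=1.0)
    error_rate: float = Field(default=0.001, ge=0.0, le=0.01)
    compartment_purities: Dict[str, CompartmentMix] = Field(
        default_factory=_default_purities
    )
    include_b_subclone: bool = True
    n_cases: int = Field(default=10, ge=1)
    n_control_sites: int = Field(default=5, ge=0)
    n_snp_sites: int = Field(default=2, ge=0)
    seed: int = 0

    @model_validator(mode="after")
    def _compartments(self) -> "SimulationConfig":
        missing = set(COMPARTMENTS) - set(self.compartment_purities)
        if missing:
            raise ValueError(f"missing compartment purities: {sorted(missing)}")
        return self


# gene, effect, zygosity for each clone of the default architecture
_ANCESTRAL_MUTS = [
    ("TET2", "a", Effect.nonsynonymous),
    ("TET2", "b", Effect.nonsynonymous),
    ("DNMT3A", "a", Effect.nonsynonymous),
    ("TET2", "syn", Effect.synonymous),
]
_T_MUTS = [("RHOA", "G17V", Effect.nonsynonymous), ("IDH2", "R172", Effect.nonsynonymous)]
_B_MUTS = [("NOTCH1", "a", Effect.nonsynonymous)]


def build_default_architecture(config: SimulationConfig) -> CloneTree:
    """Three-node hierarchy: ancestral epigenetic clone, T tumor subclone,
    optional B subclone, with per-compartment fractions from the
    configured purities."""
    purities = config.compartment_purities
    mutations: Dict[str, MutationSpec] = {}

    def make(specs, lineage: Lineage) -> tuple[str, ...]:
        ids = []
        for gene, tag, effect in specs:
            mut_id = f"{gene}_{tag}"
            mutations[mut_id] = MutationSpec(
                id=mut_id,
                gene=gene,
                effect=effect,
                zygosity=Zygosity.het,
                truth_lineage=_LINEAGE_TO_TRUTH[lineage],
            )
            ids.append(mut_id)
        return tuple(ids)

    nodes: Dict[str, CloneNode] = {}
    nodes["ancestral"] = CloneNode(
        id="ancestral",
        parent=None,
        lineage=Lineage.ancestral,
        mutations=make(_ANCESTRAL_MUTS, Lineage.ancestral),
        cell_fraction_by_compartment={
            c: purities[c].ancestral for c in COMPARTMENTS
        },
    )
    nodes["T_subclone"] = CloneNode(
        id="T_subclone",
        parent="ancestral",
        lineage=Lineage.T,
        mutations=make(_T_MUTS, Lineage.T),
        cell_fraction_by_compartment={
            c: purities[c].t_subclone for c in COMPARTMENTS
        },
    )
    if config.include_b_subclone:
        nodes["B_subclone"] = CloneNode(
            id="B_subclone",
            parent="ancestral",
            lineage=Lineage.B,
            mutations=make(_B_MUTS, Lineage.B),
            cell_fraction_by_compartment={
                c: purities[c].b_subclone for c in COMPARTMENTS
            },
        )
    return CloneTree(nodes=nodes, mutations=mutations)


def expected_vaf(tree: CloneTree, mutation: MutationSpec, compartment: str) -> float:
    """Expected allele frequency: carrier cell fraction times allele dosage
    (0.5 heterozygous, 1.0 homozygous)."""
    fraction = tree.carrier_fraction(mutation.id, compartment)
    dosage = 0.5 if mutation.zygosity is Zygosity.het else 1.0
    return fraction * dosage


def _error_adjusted(vaf: float, error_rate: float) -> float:
    # substitution errors hit the specific alt base a third of the time
    return vaf * (1.0 - error_rate) + (1.0 - vaf) * (error_rate / 3.0)


def _sample_site_counts(
    rng: np.random.Generator, vaf: float, depth_mean: float, error_rate: float
) -> tuple[int, int, int, int]:
    """(alt_fwd, alt_rev, depth_fwd, depth_rev) under the count model."""
    depth = int(rng.poisson(depth_mean))
    depth = max(depth, 1)
    p_alt = _error_adjusted(vaf, error_rate)
    alt = int(rng.binomial(depth, p_alt))
    alt_fwd = int(rng.binomial(alt, 0.5))
    ref_fwd = int(rng.binomial(depth - alt, 0.5))
    return alt_fwd, alt - alt_fwd, alt_fwd + ref_fwd, (alt - alt_fwd) + (depth - alt - ref_fwd)


def _locus(gene: str, mut_id: str) -> tuple[str, int]:
    # stable synthetic coordinates: one contig per gene, hashed offset
    return gene, 1000 + (zlib.crc32(mut_id.encode()) % 100_000)


def simulate_pileup(
    tree: CloneTree,
    config: SimulationConfig,
    sample: str = "case1",
    rng: Optional[np.random.Generator] = None,
) -> List[PileupSite]:
    """Targeted-sequencing pileups for every mutation in every compartment.

    Alongside the somatic mutations, emits heterozygous germline SNP
    sites (expected VAF 0.5, flagged as known SNPs) and error-only sites
    (expected VAF 0) as screening controls.  Deterministic for a fixed
    generator state.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sites: List[PileupSite] = []
    for compartment in COMPARTMENTS:
        sample_label = f"{sample}:{compartment}"
        for mut_id in sorted(tree.mutations):
            mut = tree.mutations[mut_id]
            vaf = expected_vaf(tree, mut, compartment)
            af, ar, df, dr = _sample_site_counts(
                rng, vaf, config.depth_mean, config.error_rate
            )
            contig, pos = _locus(mut.gene, mut_id)
            sites.append(
                PileupSite(
                    sample=sample_label,
                    contig=contig,
                    pos=pos,
                    ref="A",
                    alt="G",
                    alt_fwd=af,
                    alt_rev=ar,
                    depth_fwd=df,
                    depth_rev=dr,
                    effect=mut.effect,
                    known_snp=False,
                )
            )
        for i in range(config.n_snp_sites):
            af, ar, df, dr = _sample_site_counts(
                rng, 0.5, config.depth_mean, config.error_rate
            )
            sites.append(
                PileupSite(
                    sample=sample_label,
                    contig="SNP",
                    pos=1000 + i,
                    ref="C",
                    alt="T",
                    alt_fwd=af,
                    alt_rev=ar,
                    depth_fwd=df,
                    depth_rev=dr,
                    effect=Effect.nonsynonymous,
                    known_snp=True,
                )
            )
        for i in range(config.n_control_sites):
            af, ar, df, dr = _sample_site_counts(
                rng, 0.0, config.depth_mean, config.error_rate
            )
            sites.append(
                PileupSite(
                    sample=sample_label,
                    contig="CTRL",
                    pos=1000 + i,
                    ref="G",
                    alt="A",
                    alt_fwd=af,
                    alt_rev=ar,
                    depth_fwd=df,
                    depth_rev=dr,
                    effect=Effect.nonsynonymous,
                    known_snp=False,
                )
            )
    return sites


@dataclass(frozen=True)
class AmpliconMeasurement:
    """One mutation's amplicon deep-sequencing counts in one compartment."""

    sample: str
    mutation_id: str
    compartment: str
    alt_count: int
    depth: int

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth if self.depth > 0 else 0.0


def simulate_amplicons(
    tree: CloneTree,
    config: SimulationConfig,
    sample: str = "case1",
    rng: Optional[np.random.Generator] = None,
) -> List[AmpliconMeasurement]:
    """Amplicon validation counts for every mutation in every compartment."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out: List[AmpliconMeasurement] = []
    for compartment in COMPARTMENTS:
        for mut_id in sorted(tree.mutations):
            mut = tree.mutations[mut_id]
            vaf = expected_vaf(tree, mut, compartment)
            depth = max(int(rng.poisson(config.amplicon_depth_mean)), 1)
            alt = int(rng.binomial(depth, _error_adjusted(vaf, config.error_rate)))
            out.append(
                AmpliconMeasurement(
                    sample=sample,
                    mutation_id=mut_id,
                    compartment=compartment,
                    alt_count=alt,
                    depth=depth,
                )
            )
    return out


_V_GENES = ["IGHV1-2", "IGHV3-21", "IGHV3-23", "IGHV3-30", "IGHV4-34", "IGHV6-1"]
_D_GENES = ["D2-2", "D3-3", "D3-10", "D4-17", None]
_J_GENES = ["J1", "J2", "J3", "J4", "J5", "J6"]
_AA = string.ascii_uppercase.replace("B", "").replace("J", "").replace(
    "O", ""
).replace("U", "").replace("X", "").replace("Z", "")


def _mutate_sequence(
    seq: str, substitution_rate: float, rng: np.random.Generator
) -> str:
    """Substitute each position with probability `substitution_rate`,
    always to a different base (so realized identity tracks the rate)."""
    bases = list(seq)
    hit = rng.random(len(bases)) < substitution_rate
    for i in np.nonzero(hit)[0]:
        choices = [b for b in "ACGT" if b != bases[i]]
        bases[i] = choices[rng.integers(3)]
    return "".join(bases)


def _random_junction(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        core = "".join(rng.choice(list(_AA), size=int(rng.integers(8, 20))))
        junction = f"CAR{core}W"
        if junction not in used:
            used.add(junction)
            return junction


def simulate_igh_colonies(
    n_colonies: int,
    clone_fractions: Sequence[float],
    target_identity: float,
    seed: int,
    sample: str = "case1",
    germline_refs: Optional[Mapping[str, str]] = None,
) -> List[ColonySequence]:
    """Subcloned IgH colonies with planted clonal expansions.

    Each entry of ``clone_fractions`` plants one expanded clone holding
    ``round(fraction * n_colonies)`` colonies that share a single V/D/J
    rearrangement, junction and hypermutated V sequence; the remainder
    is a polyclonal background of colonies with distinct junctions.
    ``target_identity`` sets the percent germline identity of the
    mutated V segments (100 leaves them germline).
    """
    if n_colonies < 1:
        raise ValueError("n_colonies must be >= 1")
    if not 0.0 < target_identity <= 100.0:
        raise ValueError("target_identity must be in (0, 100]")
    if sum(clone_fractions) > 1.0 + 1e-9:
        raise ValueError("clone_fractions must sum to <= 1")
    rng = np.random.default_rng(seed)
    refs = dict(germline_refs) if germline_refs else load_germline_v_references()
    sub_rate = (100.0 - target_identity) / 100.0
    used_junctions: set[str] = set()
    colonies: List[ColonySequence] = []
    colony_no = 0

    def next_id() -> str:
        nonlocal colony_no
        colony_no += 1
        return f"{sample}_colony{colony_no:02d}"

    for fraction in clone_fractions:
        size = int(round(fraction * n_colonies))
        if size < 1:
            continue
        v_gene = str(rng.choice(_V_GENES))
        d_gene = _D_GENES[int(rng.integers(len(_D_GENES)))]
        j_gene = str(rng.choice(_J_GENES))
        junction = _random_junction(rng, used_junctions)
        v_seq = _mutate_sequence(refs[v_gene], sub_rate, rng)
        for _ in range(size):
            colonies.append(
                ColonySequence(
                    sample=sample,
                    colony_id=next_id(),
                    v_gene=v_gene,
                    d_gene=d_gene,
                    j_gene=j_gene,
                    junction_aa=junction,
                    v_sequence=v_seq,
                )
            )
    while len(colonies) < n_colonies:
        v_gene = str(rng.choice(_V_GENES))
        colonies.append(
            ColonySequence(
                sample=sample,
                colony_id=next_id(),
                v_gene=v_gene,
                d_gene=_D_GENES[int(rng.integers(len(_D_GENES)))],
                j_gene=str(rng.choice(_J_GENES)),
                junction_aa=_random_junction(rng, used_junctions),
                v_sequence=_mutate_sequence(refs[v_gene], sub_rate, rng),
            )
        )
    return colonies
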