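"""B-cell clonality and somatic hypermutation from IgH VDJ colony sequences.

After multiplex IgH PCR, a polyclonal Sanger trace is resolved by
subcloning: individual colonies are sequenced and colonies sharing an
identical V/D/J segment usage and junction amino-acid sequence are taken
as one expanded B-cell clone.  Each clone's rearranged V segment is
aligned to its closest germline IGHV reference; a germline identity
below 98% marks the clone as somatically hypermutated ("mutated"),
98% or above as unmutated.

Samples whose direct Sanger sequence was already clean are monoclonal
without subcloning; with colonies, one or more expanded clones against
a polyclonal background is oligoclonal, and no expansion is polyclonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner

__all__ = [
    "ColonySequence",
    "CloneGroup",
    "MutationStatus",
    "ClonalityCall",
    "ClonalityResult",
    "load_germline_v_references",
    "germline_identity",
    "call_mutation_status",
    "group_clones",
    "call_clonality",
]

MUTATED_IDENTITY_THRESHOLD = 98.0  # percent; strictly below => mutated


@dataclass(frozen=True)
class ColonySequence:
    """One subcloned IgH colony: segment usage, junction, V sequence.

    ``d_gene`` may be ``None`` — short or heavily mutated D segments are
    often not assignable.
    """

    sample: str
    colony_id: str
    v_gene: str
    d_gene: Optional[str]
    j_gene: str
    junction_aa: str
    v_sequence: str

    def __post_init__(self) -> None:
        if not self.junction_aa:
            raise ValueError(f"colony {self.colony_id}: empty junction")
        bad = set(self.v_sequence.upper()) - set("ACGT")
        if bad:
            raise ValueError(
                f"colony {self.colony_id}: non-ACGT characters {sorted(bad)}"
            )

    @property
    def vdj_key(self) -> tuple[str, Optional[str], str, str]:
        return (self.v_gene, self.d_gene, self.j_gene, self.junction_aa)


@dataclass(frozen=True)
class CloneGroup:
    """Colonies sharing identical V/D/J usage and junction."""

    vdj_key: tuple[str, Optional[str], str, str]
    members: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.members)


class MutationStatus(str, Enum):
    mutated = "mutated"
    unmutated = "unmutated"


class ClonalityCall(str, Enum):
    monoclonal = "monoclonal"
    oligoclonal = "oligoclonal"
    polyclonal = "polyclonal"


@dataclass(frozen=True)
class ClonalityResult:
    sample: str
    call: ClonalityCall
    clones: tuple[CloneGroup, ...]
    # per expanded clone, parallel to `clones`
    identities: tuple[float, ...] = ()
    mutation_status: tuple[MutationStatus, ...] = ()
    best_refs: tuple[str, ...] = ()


def load_germline_v_references(path=None) -> dict[str, str]:
    """Germline IGHV reference set as {segment label: sequence}.

    With no ``path``, loads the synthetic germline V segments packaged
    with this module (so the pipeline runs without network access).
    """
    if path is None:
        ref = resources.files("clonarch.data") / "germline_v_synthetic.fasta"
        with ref.open() as handle:
            records = list(SeqIO.parse(handle, "fasta"))
    else:
        records = list(SeqIO.parse(str(path), "fasta"))
    return {rec.id: str(rec.seq).upper() for rec in records}


def _aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def germline_identity(
    v_sequence: str, germline_refs: Mapping[str, str]
) -> tuple[str, float]:
    """Percent identity of a rearranged V segment to its closest germline.

    The query is globally aligned against every reference (match +1,
    mismatch -1, gap -2); identity is 100 x matches / aligned columns of
    the best-scoring pair, gap columns included in the denominator,
    reported to one decimal.

    Returns ``(best reference label, identity percent)``.
    """
    if not germline_refs:
        raise ValueError("empty germline reference set")
    if not v_sequence:
        raise ValueError("empty query sequence")
    aligner = _aligner()
    query = v_sequence.upper()
    best_label, best_score, best_identity = None, None, 0.0
    for label in sorted(germline_refs):
        alignment = aligner.align(query, germline_refs[label])[0]
        if best_score is None or alignment.score > best_score:
            counts = alignment.counts()
            best_label = label
            best_score = alignment.score
            best_identity = 100.0 * counts.identities / alignment.length
    assert best_label is not None
    return best_label, round(best_identity, 1)


def call_mutation_status(identity: float) -> MutationStatus:
    """Somatic hypermutation status: mutated iff identity < 98.0 strictly."""
    if not 0.0 <= identity <= 100.0:
        raise ValueError(f"identity {identity} outside [0, 100]")
    if identity < MUTATED_IDENTITY_THRESHOLD:
        return MutationStatus.mutated
    return MutationStatus.unmutated


def group_clones(
    colonies: Sequence[ColonySequence], min_clone_size: int = 2
) -> list[CloneGroup]:
    """Expanded clones: groups of >= min_clone_size colonies with one
    exact V/D/J + junction key, largest first (ties broken by key)."""
    if min_clone_size < 2:
        raise ValueError("min_clone_size must be >= 2")
    by_key: dict[tuple, list[str]] = {}
    for colony in colonies:
        by_key.setdefault(colony.vdj_key, []).append(colony.colony_id)
    groups = [
        CloneGroup(vdj_key=key, members=tuple(members))
        for key, members in by_key.items()
        if len(members) >= min_clone_size
    ]
    groups.sort(key=lambda g: (-g.size, tuple(str(k) for k in g.vdj_key)))
    return groups


def call_clonality(
    colonies: Sequence[ColonySequence],
    direct_sequence_monoclonal: bool = False,
    min_clone_size: int = 2,
    germline_refs: Optional[Mapping[str, str]] = None,
    sample: Optional[str] = None,
) -> ClonalityResult:
    """Clonality of the infiltrating B-cell population of one sample.

    A clean direct Sanger sequence is monoclonal and needs no colonies.
    Otherwise colonies are grouped; any expanded clone makes the sample
    oligoclonal, none makes it polyclonal.  Expanded clones are scored
    for germline identity and hypermutation status when references are
    provided (the packaged synthetic set by default).
    """
    if sample is None:
        sample = colonies[0].sample if colonies else "unknown"
    if direct_sequence_monoclonal:
        return ClonalityResult(
            sample=sample, call=ClonalityCall.monoclonal, clones=()
        )
    if not colonies:
        raise ValueError(
            "no colonies and direct sequencing not monoclonal: nothing to call"
        )
    clones = group_clones(colonies, min_clone_size=min_clone_size)
    call = ClonalityCall.oligoclonal if clones else ClonalityCall.polyclonal
    refs = dict(germline_refs) if germline_refs else load_germline_v_references()
    seq_by_id = {c.colony_id: c.v_sequence for c in colonies}
    identities, statuses, best_refs = [], [], []
    for clone in clones:
        ref, ident = germline_identity(seq_by_id[clone.members[0]], refs)
        identities.append(ident)
        statuses.append(call_mutation_status(ident))
        best_refs.append(ref)
    return ClonalityResult(
        sample=sample,
        call=call,
        clones=tuple(clones),
        identities=tuple(identities),
        mutation_status=tuple(statuses),
        best_refs=tuple(best_refs),
    )
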