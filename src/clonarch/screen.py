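"""Somatic variant screening from per-site pileup summaries.

Targeted-sequencing pileups (stranded alt/total read counts plus an
annotation effect class and a known-SNP flag) are passed through a fixed
cascade of six rules that together extract candidate somatic mutations
in a cohort without matched normals:

1. variant allele frequency (VAF) strictly above 0.02;
2. more than 6 alt reads out of more than 10 total reads;
3. alt support on both the forward and the reverse strand;
4. not synonymous;
5. not a known single-nucleotide polymorphism;
6. VAF outside the heterozygous-germline window [0.45, 0.55].

Rules are applied in this order and every input site is returned as a
:class:`VariantCandidate` annotated with the first failing rule, so the
screen is a partition of its input, never a subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

__all__ = [
    "Effect",
    "RemovalReason",
    "PileupSite",
    "VariantCandidate",
    "ScreenThresholds",
    "compute_vaf",
    "screen_site",
    "screen_variants",
]


class Effect(str, Enum):
    """Annotation effect class of a variant (coding consequence)."""

    nonsynonymous = "nonsynonymous"
    synonymous = "synonymous"


class RemovalReason(str, Enum):
    """First rule of the cascade that a removed site failed."""

    low_vaf = "low_vaf"
    low_support = "low_support"
    single_strand = "single_strand"
    synonymous = "synonymous"
    known_snp = "known_snp"
    germline_window = "germline_window"


@dataclass(frozen=True)
class PileupSite:
    """Per-site stranded read counts, the unit of variant screening."""

    sample: str
    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    alt_fwd: int
    alt_rev: int
    depth_fwd: int
    depth_rev: int
    effect: Effect
    known_snp: bool

    def __post_init__(self) -> None:
        if min(self.alt_fwd, self.alt_rev, self.depth_fwd, self.depth_rev) < 0:
            raise ValueError(f"negative read count at {self.contig}:{self.pos}")
        if self.alt_fwd > self.depth_fwd or self.alt_rev > self.depth_rev:
            raise ValueError(
                f"alt count exceeds depth at {self.contig}:{self.pos}"
            )

    @property
    def alt_total(self) -> int:
        return self.alt_fwd + self.alt_rev

    @property
    def depth_total(self) -> int:
        return self.depth_fwd + self.depth_rev


@dataclass(frozen=True)
class VariantCandidate:
    """A screened site: its VAF and whether/why it was removed."""

    site: PileupSite
    vaf: float
    removal_reason: Optional[RemovalReason] = None

    @property
    def status(self) -> str:
        return "retained" if self.removal_reason is None else "removed"

    @property
    def retained(self) -> bool:
        return self.removal_reason is None


@dataclass(frozen=True)
class ScreenThresholds:
    """Cascade thresholds. Defaults encode the published filter.

    ``min_alt_reads``/``min_depth`` are the smallest passing counts:
    "more than 6 of more than 10" reads strictly, i.e. alt >= 7 of
    depth >= 11.  The germline window is inclusive on both ends.
    """

    min_vaf_exclusive: float = 0.02
    min_alt_reads: int = 7
    min_depth: int = 11
    germline_low: float = 0.45
    germline_high: float = 0.55


def compute_vaf(site: PileupSite) -> float:
    """Combined-strand variant allele frequency (alt reads / total reads).

    Raises ``ValueError`` on zero total depth, where the frequency is
    undefined.
    """
    depth = site.depth_total
    if depth < 1:
        raise ValueError(
            f"zero total depth at {site.contig}:{site.pos}; VAF undefined"
        )
    return site.alt_total / depth


def screen_site(
    site: PileupSite, thresholds: ScreenThresholds = ScreenThresholds()
) -> VariantCandidate:
    """Run one site through the cascade; report the first failing rule."""
    vaf = compute_vaf(site)
    reason: Optional[RemovalReason] = None
    if not vaf > thresholds.min_vaf_exclusive:
        reason = RemovalReason.low_vaf
    elif not (
        site.alt_total >= thresholds.min_alt_reads
        and site.depth_total >= thresholds.min_depth
    ):
        reason = RemovalReason.low_support
    elif not (site.alt_fwd >= 1 and site.alt_rev >= 1):
        reason = RemovalReason.single_strand
    elif site.effect is Effect.synonymous:
        reason = RemovalReason.synonymous
    elif site.known_snp:
        reason = RemovalReason.known_snp
    elif thresholds.germline_low <= vaf <= thresholds.germline_high:
        reason = RemovalReason.germline_window
    return VariantCandidate(site=site, vaf=vaf, removal_reason=reason)


def screen_variants(
    sites: Iterable[PileupSite],
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> list[VariantCandidate]:
    """Screen every site; the output is a partition of the input.

    Each input site appears exactly once, either retained (all six rules
    satisfied) or removed with the first failing rule recorded.
    """
    return [screen_site(s, thresholds) for s in sites]
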