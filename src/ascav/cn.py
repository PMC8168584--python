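"""Copy-number-aware variant interpretation: mutation copy number,
early/late timing relative to gains, and whole-genome-doubling status.

The mutation copy number (mcn) — the number of chromosome copies
carrying a variant — is estimated from the variant allele frequency, the
segment's total tumor copy number and the sample purity as
``mcn = round(n_tot * VAF / purity)``.  In segments where one allele was
gained while the other was lost (LOH) or where both alleles carry >= 2
copies, a variant that predates the gain is present on every duplicated
copy (mcn >= 2, "early") while one arising after is present once
(mcn = 1, "late"); other copy-number contexts cannot distinguish the two
scenarios and are labelled "na".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CopyNumberSegment",
    "MutationTiming",
    "mutation_copy_number",
    "time_variant",
    "classify_wgd",
    "read_segments_tsv",
]


@dataclass(frozen=True)
class CopyNumberSegment:
    """One allele-specific copy-number segment (ASCAT-style)."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    n_major: int
    n_minor: int
    purity: float = 1.0

    def __post_init__(self):
        if self.n_minor < 0 or self.n_major < self.n_minor:
            raise ValueError("require n_major >= n_minor >= 0")
        if not (0 < self.purity <= 1):
            raise ValueError("purity must lie in (0, 1]")

    @property
    def n_tot(self) -> int:
        return self.n_major + self.n_minor

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class MutationTiming:
    chrom: str
    pos: int
    vaf: float
    mcn: int
    timing_class: str  # early | late | na
    inconsistent: bool = False


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def mutation_copy_number(
    n_tot: int, vaf: float, purity: float = 1.0, n_major: int | None = None
) -> int:
    """Rounded number of chromosome copies carrying the variant.

    mcn = n_tot * vaf / purity, rounded half-away-from-zero, floored at
    0, and capped at n_major when the segment's major copy number is
    supplied (a variant cannot sit on more copies than the fuller allele
    provides).
    """
    if purity <= 0 or purity > 1:
        raise ValueError("purity must lie in (0, 1]")
    if n_tot < 1:
        raise ValueError("n_tot must be >= 1")
    if not (0 <= vaf <= 1):
        raise ValueError("VAF must lie in [0, 1]")
    mcn = _round_half_away(n_tot * vaf / purity)
    mcn = max(mcn, 0)
    if n_major is not None:
        mcn = min(mcn, n_major)
    return mcn


def time_variant(mcn: int, n_major: int, n_minor: int) -> str:
    """Early/late classification of a variant relative to a gain.

    Timing is attempted only where the two scenarios are separable:
    LOH with a gained major allele (n_minor = 0, n_major >= 2) or gains
    on both alleles (n_minor >= 2).  There mcn >= 2 means the variant
    predates the duplication ("early") and mcn = 1 postdates it
    ("late"); every other context returns "na".  An mcn exceeding
    n_major is inconsistent with the segment and also yields "na".
    """
    if n_minor < 0 or n_major < n_minor:
        raise ValueError("require n_major >= n_minor >= 0")
    if mcn > n_major:
        return "na"  # inconsistent with the copy-number context
    timeable = (n_minor == 0 and n_major >= 2) or n_minor >= 2
    if not timeable:
        return "na"
    if mcn >= 2:
        return "early"
    if mcn == 1:
        return "late"
    return "na"


def time_variants(
    table: pd.DataFrame, segments: Sequence[CopyNumberSegment], purity: float = 1.0
) -> pd.DataFrame:
    """Time a table of variants (columns chrom, pos, vaf) against segments."""
    rows = []
    for _, r in table.iterrows():
        seg = next((s for s in segments if s.contains(r["chrom"], int(r["pos"]) - 1)), None)
        if seg is None:
            rows.append({**r, "mcn": pd.NA, "timing_class": "na"})
            continue
        mcn = mutation_copy_number(seg.n_tot, float(r["vaf"]), purity)
        cls = time_variant(mcn, seg.n_major, seg.n_minor)
        rows.append({**r, "mcn": mcn, "timing_class": cls})
    return pd.DataFrame(rows)


def classify_wgd(
    ploidy: float, loh_fraction: float, c0: float = 2.9, c1: float = 2.0
) -> bool:
    """Whole-genome-doubling call from ploidy and genome LOH fraction.

    WGD iff ploidy > c0 - c1 * loh_fraction (strict; a sample exactly on
    the boundary is not called doubled).  The default constants are this
    package's substitutes for the commonly used diagonal in the
    ploidy-vs-LOH plane and are fully configurable.
    """
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    if not (0 <= loh_fraction <= 1):
        raise ValueError("loh_fraction must lie in [0, 1]")
    return ploidy > c0 - c1 * loh_fraction


def read_segments_tsv(path: str | Path, purity: float = 1.0) -> list[CopyNumberSegment]:
    """Read an ASCAT-style segment table `chrom start end nMajor nMinor`."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "nMajor", "nMinor"}
    if not required <= set(df.columns):
        raise ValueError(f"segment table must have columns {sorted(required)}")
    return [
        CopyNumberSegment(
            chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            n_major=int(r.nMajor), n_minor=int(r.nMinor), purity=purity,
        )
        for r in df.itertuples()
    ]
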