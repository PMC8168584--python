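"""Peak consolidation and allelic read counting at phased het sites.

Summits from peak calling are extended symmetrically (default 250 bp,
giving 501-bp regions), pooled across the reference and both haplotype
alignments, and consolidated by iterative score-ranked selection: the
highest-scoring peak is kept and every peak overlapping it removed,
repeatedly, so the final set is non-overlapping and each retained peak is
one input peak verbatim.

Allele counts at a het variant inside a peak come from the haplotype-
exclusive read sets only: a hap1-exclusive read covering the (lifted)
site contributes to hap1_count iff its base matches the hap1 allele.
Reads carrying a third base (sequencing error) count for neither allele.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .genome import HaplotypeGenome, PhasedVariant

__all__ = [
    "Assay",
    "Peak",
    "AlleleCountRecord",
    "SimulatedRead",
    "extend_summits",
    "consolidate_peaks",
    "count_alleles",
    "filter_min_coverage",
    "flag_inconsistent_peaks",
    "read_summits_bed",
    "write_counts_tsv",
    "read_counts_tsv",
]


class Assay(str, enum.Enum):
    ATAC = "ATAC"
    RNA = "RNA"
    CHIP_H3K27AC = "CHIP_H3K27AC"
    CHIP_TF = "CHIP_TF"


#: Minimum total allelic depth per assay ("at least six reads" for
#: ATAC/ChIP, "at least 10" for RNA).
MIN_COVERAGE: dict[Assay, int] = {
    Assay.ATAC: 6,
    Assay.CHIP_H3K27AC: 6,
    Assay.CHIP_TF: 6,
    Assay.RNA: 10,
}


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int  # 0-based half-open
    end: int
    summit: int
    score: float
    peak_id: str = ""

    def __post_init__(self):
        if not (self.start <= self.summit < self.end):
            raise ValueError(f"summit {self.summit} outside [{self.start}, {self.end})")

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class AlleleCountRecord:
    """Allelic counts at one phased het site for one assay."""

    variant: PhasedVariant
    assay: Assay
    hap1_count: int
    hap2_count: int
    wgs_a: int  # WGS reads supporting the hap1 allele (#A)
    wgs_b: int  # WGS reads supporting the hap2 allele (#B)
    peak_id: str | None = None

    @property
    def depth(self) -> int:
        return self.hap1_count + self.hap2_count


def extend_summits(
    summits: Sequence[Peak] | Sequence[tuple],
    flank: int = 250,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[Peak]:
    """Extend each summit by `flank` bp on both sides (slopBed semantics),
    giving 2*flank + 1 bp regions, clipped at chromosome ends."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    out = []
    for s in summits:
        if not isinstance(s, Peak):
            chrom, summit, score = s[0], int(s[1]), float(s[2]) if len(s) > 2 else 0.0
            pid = s[3] if len(s) > 3 else f"{chrom}:{summit}"
            s = Peak(chrom=chrom, start=summit, end=summit + 1, summit=summit, score=score, peak_id=pid)
        size = None if chrom_sizes is None else chrom_sizes.get(s.chrom)
        if size is not None and not (0 <= s.summit < size):
            raise ValueError(f"summit {s.chrom}:{s.summit} outside chromosome (size {size})")
        start = max(0, s.summit - flank)
        end = s.summit + flank + 1
        if size is not None:
            end = min(end, size)
        out.append(replace(s, start=start, end=end))
    return out


def consolidate_peaks(*peak_sets: Iterable[Peak]) -> list[Peak]:
    """Iterative score-ranked selection over the pooled peak sets.

    Repeatedly keep the highest-scoring remaining peak and drop every
    peak overlapping it.  Ties broken by (chrom, start, peak_id) for
    determinism.  The result is sorted by coordinate.
    """
    pool = [p for ps in peak_sets for p in ps]
    pool.sort(key=lambda p: (-p.score, p.chrom, p.start, p.peak_id))
    trees: dict[str, IntervalTree] = {}
    kept: list[Peak] = []
    for p in pool:
        tree = trees.setdefault(p.chrom, IntervalTree())
        if tree.overlaps(p.start, p.end):
            continue
        tree[p.start : p.end] = p
        kept.append(p)
    kept.sort(key=lambda p: (p.chrom, p.start))
    return kept


@dataclass(frozen=True)
class SimulatedRead:
    """A minimal aligned read: sequence placed at a haplotype coordinate."""

    read_id: str
    chrom: str
    start: int  # 0-based, in the coordinates of its exclusive haplotype
    seq: str

    def base_at(self, pos: int) -> str | None:
        off = pos - self.start
        if 0 <= off < len(self.seq):
            return self.seq[off]
        return None


@dataclass
class CountingReport:
    records: list[AlleleCountRecord]
    excluded: list[tuple[PhasedVariant, str]] = field(default_factory=list)


def count_alleles(
    hap1_reads: Sequence[SimulatedRead],
    hap2_reads: Sequence[SimulatedRead],
    variants: Sequence[PhasedVariant],
    hap1: HaplotypeGenome,
    hap2: HaplotypeGenome,
    peaks: Sequence[Peak],
    assay: Assay = Assay.ATAC,
    wgs_counts: Mapping[tuple[str, int], tuple[int, int]] | None = None,
) -> CountingReport:
    """Count allele-supporting exclusive reads at het variants inside peaks.

    Variant positions (reference coordinates) are lifted into each
    haplotype's coordinates; a read contributes iff it covers the lifted
    site and its base equals that haplotype's allele.  `wgs_counts` maps
    (chrom, pos) to the WGS (#A, #B) pair; missing sites get (0, 0).
    """
    peak_trees: dict[str, IntervalTree] = {}
    for p in peaks:
        peak_trees.setdefault(p.chrom, IntervalTree())[p.start : p.end] = p

    def index(reads: Sequence[SimulatedRead]) -> dict[str, list[SimulatedRead]]:
        d: dict[str, list[SimulatedRead]] = {}
        for r in reads:
            d.setdefault(r.chrom, []).append(r)
        for v in d.values():
            v.sort(key=lambda r: r.start)
        return d

    idx1, idx2 = index(hap1_reads), index(hap2_reads)

    def pileup_base_count(idx, chrom, hap_pos, allele) -> int:
        import bisect

        reads = idx.get(chrom, [])
        starts = [r.start for r in reads]
        hi = bisect.bisect_right(starts, hap_pos)
        n = 0
        for r in reads[:hi]:
            if r.base_at(hap_pos) == allele:
                n += 1
        return n

    report = CountingReport(records=[])
    for v in variants:
        if not v.is_het:
            continue
        tree = peak_trees.get(v.chrom)
        hits = sorted(tree[v.start]) if tree is not None else []
        if not hits:
            report.excluded.append((v, "outside-peaks"))
            continue
        peak: Peak = hits[0].data
        p1 = hap1.lift(v.chrom, v.start, "ref2hap")
        p2 = hap2.lift(v.chrom, v.start, "ref2hap")
        if p1 is None or p2 is None:
            report.excluded.append((v, "unliftable"))
            continue
        c1 = pileup_base_count(idx1, v.chrom, p1, v.allele_on(1))
        c2 = pileup_base_count(idx2, v.chrom, p2, v.allele_on(2))
        wa, wb = (wgs_counts or {}).get((v.chrom, v.pos), (0, 0))
        report.records.append(
            AlleleCountRecord(
                variant=v, assay=assay, hap1_count=c1, hap2_count=c2,
                wgs_a=wa, wgs_b=wb, peak_id=peak.peak_id,
            )
        )
    return report


def filter_min_coverage(
    records: Iterable[AlleleCountRecord],
    thresholds: Mapping[Assay, int] | None = None,
) -> list[AlleleCountRecord]:
    """Drop records whose total allelic depth is below the assay minimum."""
    thr = dict(MIN_COVERAGE)
    if thresholds:
        thr.update(thresholds)
    return [r for r in records if r.depth >= thr[r.assay]]


def flag_inconsistent_peaks(records: Iterable[AlleleCountRecord]) -> set[str]:
    """Peak ids where co-located variants disagree on the favored haplotype.

    Peaks with multiple variants are dropped downstream (motif scoring)
    when the allelic bias between their variants is inconsistent.
    """
    directions: dict[str, set[int]] = {}
    for r in records:
        if r.peak_id is None:
            continue
        d = (r.hap1_count > r.hap2_count) - (r.hap1_count < r.hap2_count)
        if d != 0:
            directions.setdefault(r.peak_id, set()).add(d)
    return {pid for pid, ds in directions.items() if len(ds) > 1}


# ---------------------------------------------------------------------------
# I/O

def read_summits_bed(path: str | Path) -> list[Peak]:
    """Read a MACS2 summits BED (chrom, start, end, name, score)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            start = int(f[1])
            out.append(
                Peak(
                    chrom=f[0], start=start, end=int(f[2]), summit=start,
                    score=float(f[4]) if len(f) > 4 else 0.0,
                    peak_id=f[3] if len(f) > 3 else f"{f[0]}:{start}",
                )
            )
    return out


_COUNT_COLS = [
    "chrom", "pos", "ref", "alt", "gt", "assay",
    "hap1_count", "hap2_count", "wgs_a", "wgs_b", "peak_id",
]


def write_counts_tsv(records: Iterable[AlleleCountRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_COUNT_COLS) + "\n")
        for r in records:
            v = r.variant
            gt = f"{v.genotype[0]}|{v.genotype[1]}"
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref_allele}\t{v.alt_allele}\t{gt}\t"
                f"{r.assay.value}\t{r.hap1_count}\t{r.hap2_count}\t"
                f"{r.wgs_a}\t{r.wgs_b}\t{r.peak_id or '.'}\n"
            )


def read_counts_tsv(path: str | Path) -> list[AlleleCountRecord]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _COUNT_COLS:
            raise ValueError(f"unexpected counts header {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            g1, g2 = f[4].split("|")
            v = PhasedVariant(
                chrom=f[0], pos=int(f[1]), ref_allele=f[2], alt_allele=f[3],
                genotype=(int(g1), int(g2)),
            )
            out.append(
                AlleleCountRecord(
                    variant=v, assay=Assay(f[5]),
                    hap1_count=int(f[6]), hap2_count=int(f[7]),
                    wgs_a=int(f[8]), wgs_b=int(f[9]),
                    peak_id=None if f[10] == "." else f[10],
                )
            )
    return out
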