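"""Haplotype-of-origin assignment for reads aligned to both haplotypes.

Each read is aligned once against each personalized haplotype genome; the
better alignment decides its haplotype of origin.  Alignment quality is
compared lexicographically on (mapping quality, CIGAR matched bases,
mismatch count) — higher MAPQ wins, then more matched bases, then fewer
mismatches; a read equal on all three tiers maps "commonly".  Commonly
mapping reads whose two alignment loci lift to different reference
locations are discarded as ambiguous.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .genome import CoordinateMap

__all__ = [
    "AlignmentMetrics",
    "Label",
    "ReadAssignment",
    "AssignmentResult",
    "classify_read",
    "ambiguity_filter",
    "assign_all",
    "read_metrics_tsv",
    "read_metrics_sam",
    "write_partition_summary",
]


class Label(str, enum.Enum):
    HAP1_EXCLUSIVE = "HAP1_EXCLUSIVE"
    HAP2_EXCLUSIVE = "HAP2_EXCLUSIVE"
    COMMON = "COMMON"
    DISCARDED = "DISCARDED"


@dataclass(frozen=True)
class AlignmentMetrics:
    """Per-read alignment quality against one haplotype."""

    read_id: str
    mapq: int
    matched_bases: int  # sum of CIGAR M-operation lengths
    mismatches: int  # XM/NM-style mismatch count
    chrom: str
    start: int  # 0-based, haplotype coordinates
    is_duplicate: bool = False

    def key(self) -> tuple[int, int, int]:
        """Sort key: larger is better (mapq, matched, -mismatches)."""
        return (self.mapq, self.matched_bases, -self.mismatches)


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    label: Label
    reason: str = ""


def classify_read(a1: AlignmentMetrics, a2: AlignmentMetrics) -> Label:
    """Compare the two haplotype alignments of one read.

    Tie-break order: mapq (higher wins), matched bases (more wins),
    mismatches (fewer wins); equal on all tiers -> COMMON.
    """
    if a1.read_id != a2.read_id:
        raise ValueError(f"read_id mismatch: {a1.read_id!r} vs {a2.read_id!r}")
    k1, k2 = a1.key(), a2.key()
    if k1 > k2:
        return Label.HAP1_EXCLUSIVE
    if k2 > k1:
        return Label.HAP2_EXCLUSIVE
    return Label.COMMON


def ambiguity_filter(
    a1: AlignmentMetrics,
    a2: AlignmentMetrics,
    maps1: Mapping[str, CoordinateMap],
    maps2: Mapping[str, CoordinateMap],
    slack: int = 0,
) -> tuple[bool, str]:
    """Check that both alignments of a common read lift to the same
    reference locus.  Returns (keep, reason)."""
    if a1.chrom not in maps1 or a2.chrom not in maps2:
        return False, "unmappable"
    r1 = maps1[a1.chrom].lift(a1.start, "hap2ref")
    r2 = maps2[a2.chrom].lift(a2.start, "hap2ref")
    if r1 is None or r2 is None:
        return False, "unmappable"
    if a1.chrom != a2.chrom or abs(r1 - r2) > slack:
        return False, "discordant-liftover"
    return True, ""


@dataclass
class AssignmentResult:
    assignments: list[ReadAssignment]
    summary: Counter
    n_duplicates: int

    def read_ids(self, label: Label) -> list[str]:
        return [a.read_id for a in self.assignments if a.label is label]


def assign_all(
    pairs: Iterable[tuple[AlignmentMetrics | None, AlignmentMetrics | None]],
    maps1: Mapping[str, CoordinateMap] | None = None,
    maps2: Mapping[str, CoordinateMap] | None = None,
    slack: int = 0,
    remove_duplicates: bool = True,
) -> AssignmentResult:
    """Partition a stream of alignment pairs into the four read sets.

    A read present in only one haplotype's alignments is exclusive to
    that haplotype (reason "single-mapping").  Duplicates — reads flagged
    as such, or sharing both alignment loci with an earlier read — are
    removed before counting, so the four label counts sum to the number
    of unique reads.  If coordinate maps are supplied, COMMON reads with
    discordant lifted loci are DISCARDED.
    """
    assignments: list[ReadAssignment] = []
    seen_loci: set[tuple] = set()
    n_dup = 0
    for a1, a2 in pairs:
        if a1 is None and a2 is None:
            continue
        if a1 is not None and a2 is not None and a1.read_id != a2.read_id:
            raise ValueError(f"read_id mismatch: {a1.read_id!r} vs {a2.read_id!r}")
        rid = (a1 or a2).read_id
        if remove_duplicates:
            if (a1 is not None and a1.is_duplicate) or (a2 is not None and a2.is_duplicate):
                n_dup += 1
                continue
            locus_key = (
                (a1.chrom, a1.start) if a1 is not None else None,
                (a2.chrom, a2.start) if a2 is not None else None,
            )
            if locus_key in seen_loci:
                n_dup += 1
                continue
            seen_loci.add(locus_key)
        if a1 is None:
            assignments.append(ReadAssignment(rid, Label.HAP2_EXCLUSIVE, "single-mapping"))
            continue
        if a2 is None:
            assignments.append(ReadAssignment(rid, Label.HAP1_EXCLUSIVE, "single-mapping"))
            continue
        label = classify_read(a1, a2)
        reason = ""
        if label is Label.COMMON and maps1 is not None and maps2 is not None:
            keep, reason = ambiguity_filter(a1, a2, maps1, maps2, slack=slack)
            if not keep:
                label = Label.DISCARDED
        assignments.append(ReadAssignment(rid, label, reason))
    summary = Counter(a.label for a in assignments)
    for lab in Label:
        summary.setdefault(lab, 0)
    return AssignmentResult(assignments=assignments, summary=summary, n_duplicates=n_dup)


# ---------------------------------------------------------------------------
# I/O

_TSV_COLUMNS = ["read_id", "mapq", "matched_bases", "mismatches", "chrom", "pos", "is_dup"]


def read_metrics_tsv(path: str | Path) -> dict[str, AlignmentMetrics]:
    """Read the documented alignment-metrics TSV dialect.

    Columns (tab-separated, with header):
    ``read_id mapq matched_bases mismatches chrom pos is_dup``;
    ``pos`` is 0-based; ``is_dup`` is 0/1.
    """
    out: dict[str, AlignmentMetrics] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TSV_COLUMNS:
            raise ValueError(f"unexpected metrics header {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out[f[0]] = AlignmentMetrics(
                read_id=f[0], mapq=int(f[1]), matched_bases=int(f[2]),
                mismatches=int(f[3]), chrom=f[4], start=int(f[5]),
                is_duplicate=f[6] == "1",
            )
    return out


def read_metrics_sam(path: str | Path) -> dict[str, AlignmentMetrics]:
    """Extract metrics from a SAM/BAM of primary alignments.

    Matched bases are the summed M/=/X CIGAR lengths; the mismatch count
    comes from the XM tag (Bowtie 2) or NM as a fallback.
    """
    import pysam

    out: dict[str, AlignmentMetrics] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            matched = sum(ln for op, ln in (aln.cigartuples or []) if op in (0, 7, 8))
            if aln.has_tag("XM"):
                mism = int(aln.get_tag("XM"))
            elif aln.has_tag("NM"):
                mism = int(aln.get_tag("NM"))
            else:
                mism = 0
            out[aln.query_name] = AlignmentMetrics(
                read_id=aln.query_name, mapq=aln.mapping_quality,
                matched_bases=matched, mismatches=mism,
                chrom=aln.reference_name, start=aln.reference_start,
                is_duplicate=aln.is_duplicate,
            )
    return out


def pair_metrics(
    m1: Mapping[str, AlignmentMetrics], m2: Mapping[str, AlignmentMetrics]
) -> Iterator[tuple[AlignmentMetrics | None, AlignmentMetrics | None]]:
    """Join two per-haplotype metrics dicts by read_id."""
    for rid in sorted(set(m1) | set(m2)):
        yield m1.get(rid), m2.get(rid)


def write_partition_summary(result: AssignmentResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("label\tcount\n")
        for lab in Label:
            fh.write(f"{lab.value}\t{result.summary[lab]}\n")
        fh.write(f"DUPLICATES_REMOVED\t{result.n_duplicates}\n")
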