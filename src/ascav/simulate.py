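"""Deterministic synthetic diploid fixtures with known ground truth.

The generator emits a miniature version of everything the pipeline
consumes — reference genome, phased het variants, copy-number segments,
peaks, per-assay allele counts, per-read alignment metrics, and planted
motif gains — with a truth table tying every record to its generating
parameters.  All randomness flows through a single seeded generator, so
identical configurations produce byte-identical files.

What it emulates: phased het sites inside accessible peaks; WGS allele
counts binomial at the copy-number-determined allele fraction; assay
counts beta-binomial (configurable overdispersion, default 0.02) at a
true allelic ratio combining the genomic fraction with any planted
regulatory imbalance in odds space; CN-consistent VAFs for early/late
timing truth.  What it does not emulate: fragment-length and Tn5 bias,
base-quality structure, and real aligner behavior (alignment metrics
are exact Hamming comparisons against both haplotypes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .assignment import AlignmentMetrics
from .counting import AlleleCountRecord, Assay, Peak, SimulatedRead, extend_summits
from .genome import HaplotypeGenome, PhasedVariant, build_haplotypes, write_fasta, write_vcf
from .motifs import PWM

__all__ = [
    "SimConfig",
    "SimBundle",
    "simulate_dataset",
    "simulate_allele_counts",
    "simulate_null_counts",
    "plant_motif_gain",
    "simulate_reads",
    "betabin_sample",
]

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def betabin_sample(
    rng: np.random.Generator, n, ratio, overdispersion: float = 0.02
):
    """Beta-binomial draw with mean `ratio` and correlation `overdispersion`.

    overdispersion -> 0 recovers the plain binomial.
    """
    n = np.asarray(n)
    ratio = np.broadcast_to(np.asarray(ratio, float), n.shape)
    if overdispersion <= 0:
        return rng.binomial(n, ratio)
    s = (1.0 - overdispersion) / overdispersion
    p = rng.beta(np.maximum(ratio * s, 1e-9), np.maximum((1.0 - ratio) * s, 1e-9))
    return rng.binomial(n, p)


def _odds_combine(genomic: float, regulatory: float) -> float:
    """Combine copy-number and regulatory allele fractions in odds space."""
    o = (genomic / (1 - genomic)) * (regulatory / (1 - regulatory))
    return o / (1 + o)


@dataclass
class SimConfig:
    """Study conditions for the miniature diploid dataset.

    Defaults give 2 chromosomes x 500 kb, ~2,000 het SNVs and 200
    501-bp peaks; 10% of in-peak sites carry a planted allelic
    imbalance of 0.85, the remainder are null at the genomic ratio.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 500_000
    het_snv_rate: float = 0.002
    indel_rate: float = 5e-5
    # per-chromosome equal-span (n_major, n_minor) profile
    cn_profile: tuple[tuple[int, int], ...] = ((1, 1), (2, 1), (2, 2), (3, 1))
    purity: float = 1.0
    n_peaks: int = 200
    peak_flank: int = 250
    planted_ascav_fraction: float = 0.1
    true_imbalance_ratio: float = 0.85
    wgs_depth: int = 40
    atac_depth: int = 30
    rna_depth: int = 30
    overdispersion: float = 0.02
    planted_motif: PWM | None = None
    n_motif_peaks: int = 0

    def __post_init__(self):
        for name in ("het_snv_rate", "indel_rate", "planted_ascav_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if min(self.wgs_depth, self.atac_depth, self.rna_depth) < 1:
            raise ValueError("depths must be >= 1")
        if self.n_peaks * (2 * self.peak_flank + 1) > self.n_chroms * self.chrom_length:
            raise ValueError("peaks exceed genome size")


@dataclass
class SimBundle:
    config: SimConfig
    reference: dict[str, str]
    variants: list[PhasedVariant]
    hap1: HaplotypeGenome
    hap2: HaplotypeGenome
    segments: pd.DataFrame  # chrom start end nMajor nMinor
    peaks: list[Peak]
    atac_records: list[AlleleCountRecord]
    rna_records: list[AlleleCountRecord]
    truth: pd.DataFrame
    out_dir: Path | None = None


def _segment_for(segments: pd.DataFrame, chrom: str, pos0: int) -> pd.Series:
    m = segments[(segments.chrom == chrom) & (segments.start <= pos0) & (pos0 < segments.end)]
    return m.iloc[0]


def simulate_dataset(config: SimConfig, out_dir: str | Path | None = None) -> SimBundle:
    """Generate the full fixture bundle; optionally write it to disk."""
    rng = np.random.default_rng(config.seed)
    reference: dict[str, str] = {}
    seg_rows = []
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        reference[chrom] = _random_seq(rng, config.chrom_length)
        n_seg = len(config.cn_profile)
        span = config.chrom_length // n_seg
        for si, (nmaj, nmin) in enumerate(config.cn_profile):
            start = si * span
            end = config.chrom_length if si == n_seg - 1 else (si + 1) * span
            seg_rows.append(
                {"chrom": chrom, "start": start, "end": end, "nMajor": nmaj, "nMinor": nmin}
            )
    segments = pd.DataFrame(seg_rows)

    # --- phased variants (het SNVs + a few simple indels); LOH segments
    # cannot carry germline het sites, so variant placement skips them.
    variants: list[PhasedVariant] = []
    truth_rows = []
    for chrom, ref_seq in reference.items():
        L = len(ref_seq)
        n_snv = rng.binomial(L, config.het_snv_rate)
        n_ind = rng.binomial(L, config.indel_rate)
        positions = rng.choice(L - 20, size=n_snv + n_ind, replace=False) + 10
        positions.sort()
        keep = np.ones(positions.size, bool)  # enforce 10-bp spacing for indel safety
        keep[1:] = np.diff(positions) >= 10
        positions = positions[keep]
        is_indel = np.zeros(positions.size, bool)
        if positions.size and n_ind:
            is_indel[rng.choice(positions.size, size=min(n_ind, positions.size), replace=False)] = True
        for p0, ind in zip(positions, is_indel):
            seg = _segment_for(segments, chrom, int(p0))
            if seg.nMinor == 0:
                continue
            ref_base = ref_seq[p0]
            gt = (1, 0) if rng.random() < 0.5 else (0, 1)
            if ind:
                if rng.random() < 0.5:  # insertion
                    alt = ref_base + _random_seq(rng, int(rng.integers(1, 4)))
                    v = PhasedVariant(chrom, int(p0) + 1, ref_base, alt, gt)
                else:  # deletion
                    dl = int(rng.integers(1, 4))
                    v = PhasedVariant(chrom, int(p0) + 1, ref_seq[p0 : p0 + 1 + dl], ref_base, gt)
            else:
                alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
                v = PhasedVariant(chrom, int(p0) + 1, ref_base, alt, gt)
            variants.append(v)

    hap1, hap2 = build_haplotypes(reference, variants)

    # --- peaks centered on a sample of SNV sites, non-overlapping
    snvs = [v for v in variants if v.kind == "snv"]
    order = rng.permutation(len(snvs))
    peaks: list[Peak] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for i in order:
        if len(peaks) >= config.n_peaks:
            break
        v = snvs[i]
        start = max(0, v.start - config.peak_flank)
        end = min(len(reference[v.chrom]), v.start + config.peak_flank + 1)
        if any(s < end and start < e for s, e in occupied.get(v.chrom, [])):
            continue
        occupied.setdefault(v.chrom, []).append((start, end))
        peaks.append(
            Peak(
                chrom=v.chrom, start=start, end=end, summit=v.start,
                score=float(rng.uniform(5, 100)), peak_id=f"peak_{len(peaks)}",
            )
        )
    peaks.sort(key=lambda p: (p.chrom, p.start))

    # --- per-site truth and counts
    peak_by_site: dict[tuple[str, int], Peak] = {}
    for p in peaks:
        for v in variants:
            if v.chrom == p.chrom and p.contains(v.start):
                peak_by_site[(v.chrom, v.pos)] = p

    atac_records, rna_records = [], []
    for v in variants:
        if not v.is_het:
            continue
        seg = _segment_for(segments, v.chrom, v.start)
        n_tot = int(seg.nMajor + seg.nMinor)
        # haplotype 1 carries the major allele of every segment
        genomic_h1 = seg.nMajor / n_tot
        peak = peak_by_site.get((v.chrom, v.pos))
        planted = peak is not None and rng.random() < config.planted_ascav_fraction
        if planted:
            reg = config.true_imbalance_ratio if rng.random() < 0.5 else 1 - config.true_imbalance_ratio
        else:
            reg = 0.5
        assay_ratio = _odds_combine(genomic_h1, reg)
        wgs_a = int(rng.binomial(config.wgs_depth, genomic_h1))
        wgs_b = config.wgs_depth - wgs_a
        # CN-consistent VAF for timing truth: early variants sit on every
        # major copy, late on one; untimeable contexts get one copy.
        timeable = (seg.nMinor == 0 and seg.nMajor >= 2) or seg.nMinor >= 2
        if timeable and seg.nMajor >= 2:
            mcn_true = int(seg.nMajor) if rng.random() < 0.5 else 1
            timing = "early" if mcn_true >= 2 else "late"
        else:
            mcn_true, timing = 1, "na"
        vaf = mcn_true * config.purity / n_tot
        if peak is not None:
            a1 = int(betabin_sample(rng, np.array(config.atac_depth), assay_ratio, config.overdispersion))
            atac_records.append(
                AlleleCountRecord(
                    variant=v, assay=Assay.ATAC, hap1_count=a1,
                    hap2_count=config.atac_depth - a1,
                    wgs_a=wgs_a, wgs_b=wgs_b, peak_id=peak.peak_id,
                )
            )
            r1 = int(betabin_sample(rng, np.array(config.rna_depth), assay_ratio, config.overdispersion))
            rna_records.append(
                AlleleCountRecord(
                    variant=v, assay=Assay.RNA, hap1_count=r1,
                    hap2_count=config.rna_depth - r1,
                    wgs_a=wgs_a, wgs_b=wgs_b, peak_id=peak.peak_id,
                )
            )
        truth_rows.append(
            {
                "chrom": v.chrom, "pos": v.pos, "kind": v.kind,
                "gt": f"{v.genotype[0]}|{v.genotype[1]}",
                "in_peak": peak is not None,
                "peak_id": peak.peak_id if peak else ".",
                "planted": planted, "true_reg_ratio": reg,
                "true_assay_ratio": assay_ratio, "genomic_h1": genomic_h1,
                "vaf": vaf, "mcn_true": mcn_true, "timing_class": timing,
            }
        )
    truth = pd.DataFrame(truth_rows)

    bundle = SimBundle(
        config=config, reference=reference, variants=variants,
        hap1=hap1, hap2=hap2, segments=segments, peaks=peaks,
        atac_records=atac_records, rna_records=rna_records, truth=truth,
    )
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(b: SimBundle, out: Path) -> None:
    from .counting import write_counts_tsv

    out.mkdir(parents=True, exist_ok=True)
    contigs = {c: len(s) for c, s in b.reference.items()}
    write_fasta(b.reference, out / "reference.fa")
    write_fasta(b.hap1.sequences, out / "genome.hap1.fa")
    write_fasta(b.hap2.sequences, out / "genome.hap2.fa")
    write_vcf(b.variants, out / "phased.vcf", contigs=contigs)
    with open(out / "peaks.bed", "w") as fh:
        for p in b.peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t{p.score:.3f}\n")
    b.segments.to_csv(out / "cn_segments.tsv", sep="\t", index=False)
    write_counts_tsv(b.atac_records, out / "counts_atac.tsv")
    write_counts_tsv(b.rna_records, out / "counts_rna.tsv")
    b.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    b.out_dir = out


def simulate_allele_counts(
    n_sites: int,
    wgs_depth: int,
    assay_depth: int,
    true_ratio,
    genomic_ratio=0.5,
    overdispersion: float = 0.02,
    assay: Assay = Assay.ATAC,
    rng: np.random.Generator | int = 0,
) -> list[AlleleCountRecord]:
    """Direct count-level fixture: n_sites records with the given truth.

    `true_ratio` and `genomic_ratio` may be scalars or length-n arrays.
    WGS counts are binomial at the genomic ratio; assay counts are
    beta-binomial at the true ratio.  Used for calibration and
    parameter-recovery studies at exactly specified depths.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    ratio = np.broadcast_to(np.asarray(true_ratio, float), (n_sites,))
    gr = np.broadcast_to(np.asarray(genomic_ratio, float), (n_sites,))
    wgs_a = rng.binomial(wgs_depth, gr)
    assay_a = betabin_sample(rng, np.full(n_sites, assay_depth), ratio, overdispersion)
    records = []
    for i in range(n_sites):
        v = PhasedVariant("chr1", i + 1, "A", "C", (1, 0))
        records.append(
            AlleleCountRecord(
                variant=v, assay=assay,
                hap1_count=int(assay_a[i]), hap2_count=assay_depth - int(assay_a[i]),
                wgs_a=int(wgs_a[i]), wgs_b=wgs_depth - int(wgs_a[i]),
                peak_id=f"peak_{i}",
            )
        )
    return records


def simulate_null_counts(
    n_sites: int,
    wgs_depth: int,
    assay_depth: int,
    genomic_ratio=0.5,
    assay: Assay = Assay.ATAC,
    rng: np.random.Generator | int = 0,
) -> list[AlleleCountRecord]:
    """Null fixture: assay counts drawn at each site's genomic ratio.

    WGS counts are binomial at the underlying `genomic_ratio`; assay
    counts are then binomial at the *observed* WGS allele fraction, the
    genomic ratio the imbalance test corrects against.  Under this null
    the test's posterior predictive is wider than the sampling
    distribution, so its p-values are conservative by construction.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    gr = np.broadcast_to(np.asarray(genomic_ratio, float), (n_sites,))
    wgs_a = rng.binomial(wgs_depth, gr)
    obs_ratio = np.clip(wgs_a / wgs_depth, 1e-9, 1 - 1e-9)
    assay_a = rng.binomial(assay_depth, obs_ratio)
    records = []
    for i in range(n_sites):
        v = PhasedVariant("chr1", i + 1, "A", "C", (1, 0))
        records.append(
            AlleleCountRecord(
                variant=v, assay=assay,
                hap1_count=int(assay_a[i]), hap2_count=assay_depth - int(assay_a[i]),
                wgs_a=int(wgs_a[i]), wgs_b=wgs_depth - int(wgs_a[i]),
                peak_id=f"peak_{i}",
            )
        )
    return records


@dataclass
class PlantedGain:
    hap1_seq: str
    hap2_seq: str
    offset: int  # variant offset within the peak sequence
    hap1_base: str
    hap2_base: str
    gain_haplotype: int  # haplotype carrying the intact motif


def plant_motif_gain(
    peak_seq: str, pwm: PWM, position: int, gain_haplotype: int = 1
) -> PlantedGain:
    """Embed a motif consensus on one haplotype and a 1-bp disruption on
    the other, returning both sequences and the phased difference.

    The disrupted base is placed at the motif's most informative
    position and chosen to minimize that position's probability, so the
    delta score between alleles is maximal for this PWM.
    """
    if position < 0 or position + len(pwm) > len(peak_seq):
        raise ValueError("motif does not fit inside the peak at this position")
    cons = pwm.consensus
    lo = pwm.log_odds
    off = int((lo.max(axis=1) - lo.min(axis=1)).argmax())
    worst = "ACGT"[int(pwm.matrix[off].argmin())]
    intact = peak_seq[:position] + cons + peak_seq[position + len(pwm) :]
    broken = intact[: position + off] + worst + intact[position + off + 1 :]
    if gain_haplotype == 1:
        h1, h2, b1, b2 = intact, broken, cons[off], worst
    else:
        h1, h2, b1, b2 = broken, intact, worst, cons[off]
    return PlantedGain(
        hap1_seq=h1, hap2_seq=h2, offset=position + off,
        hap1_base=b1, hap2_base=b2, gain_haplotype=gain_haplotype,
    )


def simulate_reads(
    hap1: HaplotypeGenome,
    hap2: HaplotypeGenome,
    chrom: str,
    n_reads: int,
    read_length: int = 50,
    hap1_fraction: float = 0.5,
    error_rate: float = 0.0,
    rng: np.random.Generator | int = 0,
    region: tuple[int, int] | None = None,
) -> tuple[list[tuple[AlignmentMetrics | None, AlignmentMetrics | None]], dict[str, int], list[SimulatedRead]]:
    """Sample reads from the two haplotypes and compute alignment metrics.

    Each read is drawn uniformly from its haplotype of origin (chosen
    with probability `hap1_fraction` for haplotype 1) and compared by
    exact Hamming distance against the corresponding window of both
    haplotypes, located through the coordinate maps.  Returns the metric
    pairs, the true origin of every read, and the reads themselves.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    seqs = {1: hap1.sequences[chrom], 2: hap2.sequences[chrom]}
    haps = {1: hap1, 2: hap2}
    lo, hi = region if region else (0, None)
    pairs: list[tuple[AlignmentMetrics | None, AlignmentMetrics | None]] = []
    origins: dict[str, int] = {}
    reads: list[SimulatedRead] = []
    for i in range(n_reads):
        origin = 1 if rng.random() < hap1_fraction else 2
        own_seq = seqs[origin]
        upper = (len(own_seq) if hi is None else hi) - read_length
        start = int(rng.integers(lo, upper + 1))
        read = list(own_seq[start : start + read_length])
        if error_rate > 0:
            errs = np.flatnonzero(rng.random(read_length) < error_rate)
            for e in errs:
                read[e] = str(rng.choice([b for b in "ACGT" if b != read[e]]))
        read_s = "".join(read)
        rid = f"read_{i}"
        origins[rid] = origin
        reads.append(SimulatedRead(read_id=rid, chrom=chrom, start=start, seq=read_s))

        def metrics(hap_id: int, pos: int) -> AlignmentMetrics:
            window = seqs[hap_id][pos : pos + read_length]
            mism = sum(a != b for a, b in zip(read_s, window)) + (read_length - len(window))
            return AlignmentMetrics(
                read_id=rid, mapq=60, matched_bases=read_length,
                mismatches=mism, chrom=chrom, start=pos,
            )

        other = 2 if origin == 1 else 1
        ref_pos = haps[origin].lift(chrom, start, "hap2ref")
        other_pos = None if ref_pos is None else haps[other].lift(chrom, ref_pos, "ref2hap")
        m_own = metrics(origin, start)
        m_other = None if other_pos is None else metrics(other, other_pos)
        pair = (m_own, m_other) if origin == 1 else (m_other, m_own)
        pairs.append(pair)
    return pairs, origins, reads
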