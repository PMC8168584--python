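"""Personalized diploid genome construction.

Builds per-haplotype genome sequences from a reference and phased
heterozygous variants, together with coordinate maps that link reference
and haplotype coordinates.  The maps play the role chain files play in a
liftOver-based workflow, but because the haplotypes are constructed here
they are exact by construction.

Coordinate conventions: all internal coordinates are 0-based half-open;
``PhasedVariant.pos`` follows VCF and is 1-based.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "PhasedVariant",
    "CoordinateMap",
    "HaplotypeGenome",
    "build_haplotypes",
    "read_fasta",
    "write_fasta",
    "read_phased_vcf",
    "write_vcf",
    "write_chain",
    "write_block_table",
]

_DNA = frozenset("ACGT")


class VariantError(ValueError):
    """Raised for variants that cannot be applied to the reference."""


@dataclass(frozen=True)
class PhasedVariant:
    """A phased variant at a single reference site.

    ``genotype`` is the ordered (hap1, hap2) pair of allele indices,
    0 = ref_allele, 1 = alt_allele; a phased het site is 0|1 or 1|0.
    ``pos`` is 1-based (VCF convention).
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    genotype: tuple[int, int]

    def __post_init__(self) -> None:
        if not set(self.ref_allele) <= _DNA or not set(self.alt_allele) <= _DNA:
            raise VariantError(
                f"{self.chrom}:{self.pos} alleles must be A/C/G/T "
                f"({self.ref_allele!r}>{self.alt_allele!r})"
            )
        if any(g not in (0, 1) for g in self.genotype):
            raise VariantError(f"{self.chrom}:{self.pos} genotype must use allele indices 0/1")

    @property
    def is_het(self) -> bool:
        return self.genotype[0] != self.genotype[1]

    @property
    def start(self) -> int:
        """0-based start of the reference span."""
        return self.pos - 1

    @property
    def end(self) -> int:
        """0-based half-open end of the reference span."""
        return self.pos - 1 + len(self.ref_allele)

    @property
    def kind(self) -> str:
        r, a = len(self.ref_allele), len(self.alt_allele)
        if r == 1 and a == 1:
            return "snv"
        if r == 1 and a > 1 and self.alt_allele[0] == self.ref_allele:
            return "ins"
        if a == 1 and r > 1 and self.ref_allele[0] == self.alt_allele:
            return "del"
        return "complex"

    def allele_on(self, haplotype: int) -> str:
        """Allele carried by haplotype 1 or 2."""
        return self.alt_allele if self.genotype[haplotype - 1] == 1 else self.ref_allele


@dataclass
class CoordinateMap:
    """Collinear block map between reference and one haplotype (one chrom).

    Each block is ``(ref_start, hap_start, length)``, 0-based half-open,
    sorted and non-overlapping on both axes.  Reference positions inside a
    deletion, and haplotype positions inside an insertion, fall between
    blocks and do not map.
    """

    chrom: str
    blocks: list[tuple[int, int, int]] = field(default_factory=list)

    def lift(self, pos: int, direction: str = "ref2hap") -> int | None:
        if direction == "ref2hap":
            src, dst = 0, 1
        elif direction == "hap2ref":
            src, dst = 1, 0
        else:
            raise ValueError(f"direction must be ref2hap or hap2ref, got {direction!r}")
        starts = [b[src] for b in self.blocks]
        i = bisect_right(starts, pos) - 1
        if i < 0:
            return None
        block = self.blocks[i]
        offset = pos - block[src]
        if offset >= block[2]:
            return None
        return block[dst] + offset

    @property
    def ref_length(self) -> int:
        b = self.blocks[-1]
        return b[0] + b[2] if self.blocks else 0

    @property
    def hap_length(self) -> int:
        b = self.blocks[-1]
        return b[1] + b[2] if self.blocks else 0


def lift_position(cmap: CoordinateMap, pos: int, direction: str = "ref2hap") -> int | None:
    """Functional wrapper around :meth:`CoordinateMap.lift`."""
    return cmap.lift(pos, direction)


@dataclass
class HaplotypeGenome:
    """One haplotype's sequences plus coordinate maps back to the reference."""

    haplotype_id: int
    sequences: dict[str, str]
    maps: dict[str, CoordinateMap]
    applied_variants: list[PhasedVariant]

    def lift(self, chrom: str, pos: int, direction: str = "ref2hap") -> int | None:
        if chrom not in self.maps:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return self.maps[chrom].lift(pos, direction)

    def extract(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][start:end]


def _build_one_haplotype(
    reference: Mapping[str, str],
    variants: list[PhasedVariant],
    haplotype: int,
) -> tuple[dict[str, str], dict[str, CoordinateMap], list[PhasedVariant]]:
    seqs: dict[str, str] = {}
    maps: dict[str, CoordinateMap] = {}
    applied: list[PhasedVariant] = []
    by_chrom: dict[str, list[PhasedVariant]] = {c: [] for c in reference}
    for v in variants:
        if v.chrom not in reference:
            raise VariantError(f"variant on unknown chromosome {v.chrom!r}")
        by_chrom[v.chrom].append(v)

    for chrom, ref_seq in reference.items():
        parts: list[str] = []
        blocks: list[tuple[int, int, int]] = []
        ref_cursor = 0  # next reference base to copy
        hap_cursor = 0  # haplotype length emitted so far
        block_ref = 0  # current collinear block start (ref axis)
        block_hap = 0

        def close_block(upto_ref: int) -> None:
            length = upto_ref - block_ref
            if length > 0:
                blocks.append((block_ref, block_hap, length))

        for v in by_chrom[chrom]:
            allele = v.allele_on(haplotype)
            if allele == v.ref_allele:
                continue  # reference on this haplotype; nothing to apply
            if v.end > len(ref_seq):
                raise VariantError(f"{chrom}:{v.pos} extends past chromosome end")
            observed = ref_seq[v.start : v.end]
            if observed != v.ref_allele:
                raise VariantError(
                    f"reference mismatch at {chrom}:{v.pos}: "
                    f"expected {v.ref_allele!r}, found {observed!r}"
                )
            if v.start < ref_cursor:
                prev = applied[-1] if applied else None
                prev_site = f"{prev.chrom}:{prev.pos}" if prev else "an earlier variant"
                raise VariantError(
                    f"overlapping variants on haplotype {haplotype}: "
                    f"{chrom}:{v.pos} overlaps {prev_site}"
                )
            kind = v.kind
            if kind == "complex":
                raise VariantError(
                    f"{chrom}:{v.pos} is a multi-nucleotide/complex variant "
                    f"({v.ref_allele}>{v.alt_allele}); only SNVs and simple indels are applied"
                )
            # copy intervening reference
            parts.append(ref_seq[ref_cursor : v.start])
            hap_cursor += v.start - ref_cursor
            if kind == "snv":
                parts.append(allele)
                hap_cursor += 1
                ref_cursor = v.start + 1
            elif kind == "ins":
                # anchor base stays collinear; inserted bases break the block
                parts.append(allele)
                close_block(v.start + 1)
                hap_cursor += len(allele)
                ref_cursor = v.start + 1
                block_ref = ref_cursor
                block_hap = hap_cursor
            else:  # del
                parts.append(allele)  # the anchor base
                hap_cursor += 1
                close_block(v.start + 1)
                ref_cursor = v.end
                block_ref = ref_cursor
                block_hap = hap_cursor
            applied.append(v)

        parts.append(ref_seq[ref_cursor:])
        hap_cursor += len(ref_seq) - ref_cursor
        close_block(len(ref_seq))
        seqs[chrom] = "".join(parts)
        maps[chrom] = CoordinateMap(chrom=chrom, blocks=blocks)
        assert len(seqs[chrom]) == hap_cursor
    return seqs, maps, applied


def build_haplotypes(
    reference: Mapping[str, str],
    variants: Iterable[PhasedVariant],
) -> tuple[HaplotypeGenome, HaplotypeGenome]:
    """Construct both haplotype genomes from a reference and phased variants.

    Variants must be sorted by (chrom, pos); SNVs and simple indels only.
    Homozygous-alt variants are applied to both haplotypes.  Reference
    mismatches and overlapping variants raise :class:`VariantError` naming
    the offending site.
    """
    reference = {c: s.upper() for c, s in reference.items()}
    vlist = sorted(variants, key=lambda v: (v.chrom, v.pos))
    haps = []
    for h in (1, 2):
        seqs, maps, applied = _build_one_haplotype(reference, vlist, h)
        haps.append(HaplotypeGenome(haplotype_id=h, sequences=seqs, maps=maps, applied_variants=applied))
    return haps[0], haps[1]


# ---------------------------------------------------------------------------
# I/O

def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into per-chromosome uppercase strings."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), sequence_always_upper=True, rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_phased_vcf(path: str | Path) -> list[PhasedVariant]:
    """Read biallelic variants with phased GT from a VCF.

    Unphased or half-missing genotypes are skipped; multi-allelic records
    raise, since phase interpretation would be ambiguous.
    """
    from cyvcf2 import VCF

    out: list[PhasedVariant] = []
    for rec in VCF(str(path)):
        if len(rec.ALT) != 1:
            raise VariantError(f"multi-allelic record at {rec.CHROM}:{rec.POS}; split first")
        g = rec.genotypes[0]  # [a, b, phased]
        if len(g) < 3 or not g[2] or g[0] < 0 or g[1] < 0:
            continue
        out.append(
            PhasedVariant(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref_allele=rec.REF.upper(),
                alt_allele=rec.ALT[0].upper(),
                genotype=(g[0], g[1]),
            )
        )
    return out


def write_vcf(variants: Iterable[PhasedVariant], path: str | Path,
              contigs: Mapping[str, int] | None = None, sample: str = "sample") -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c, n in (contigs or {}).items():
            fh.write(f"##contig=<ID={c},length={n}>\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for v in variants:
            gt = f"{v.genotype[0]}|{v.genotype[1]}"
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\tPASS\t.\tGT\t{gt}\n"
            )


def write_chain(hap: HaplotypeGenome, reference: Mapping[str, str], path: str | Path) -> None:
    """Serialize coordinate maps in UCSC chain format (ref -> haplotype)."""
    with open(path, "w") as fh:
        for chain_id, (chrom, cmap) in enumerate(hap.maps.items(), start=1):
            t_size = len(reference[chrom])
            q_size = len(hap.sequences[chrom])
            if not cmap.blocks:
                continue
            t_start = cmap.blocks[0][0]
            q_start = cmap.blocks[0][1]
            t_end = cmap.blocks[-1][0] + cmap.blocks[-1][2]
            q_end = cmap.blocks[-1][1] + cmap.blocks[-1][2]
            fh.write(
                f"chain 1000 {chrom} {t_size} + {t_start} {t_end} "
                f"{chrom} {q_size} + {q_start} {q_end} {chain_id}\n"
            )
            for i, (rs, hs, ln) in enumerate(cmap.blocks):
                if i + 1 < len(cmap.blocks):
                    nrs, nhs, _ = cmap.blocks[i + 1]
                    dt = nrs - (rs + ln)
                    dq = nhs - (hs + ln)
                    fh.write(f"{ln}\t{dt}\t{dq}\n")
                else:
                    fh.write(f"{ln}\n")
            fh.write("\n")


def write_block_table(hap: HaplotypeGenome, path: str | Path) -> None:
    """Simple TSV block table: chrom, ref_start, hap_start, length."""
    with open(path, "w") as fh:
        fh.write("chrom\tref_start\thap_start\tlength\n")
        for chrom, cmap in hap.maps.items():
            for rs, hs, ln in cmap.blocks:
                fh.write(f"{chrom}\t{rs}\t{hs}\t{ln}\n")
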