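# Methods

This note documents the models, conventions and design decisions behind
`ascav`, in the spirit of the methods documentation of statsmodels or
msprime: what each stage assumes, which knobs matter, and what the
synthetic-data tests do and do not demonstrate.

## Personalized diploid genomes

Haplotype sequences are built by substituting each phased variant's
allele into the reference, per haplotype. Only SNVs and simple indels
(VCF-style, anchor base shared) are applied; multi-nucleotide and
structural variants are rejected with an error naming the site rather
than silently skipped, because every downstream unit of analysis is a
phased SNV/indel. Homozygous-alt variants are applied to both haplotypes
but excluded from imbalance testing (only het sites are informative).
Soft-masked reference bases are uppercased on load so sequence
comparisons are deterministic.

Coordinates are 0-based half-open internally; VCF positions are 1-based;
BED intervals 0-based half-open. Each haplotype carries a block map
`(ref_start, hap_start, length)` that is exact by construction — SNVs do
not break collinearity, indels do. Lifting a position inside a deletion
(ref→hap) or an insertion (hap→ref) returns "unmapped" rather than a
nearest neighbor; round trips are the identity wherever both directions
are defined. Maps serialize both as UCSC chain files and as a plain TSV
block table.

## Haplotype read assignment

Each read is aligned once per haplotype; the two alignments are compared
lexicographically in the order **MAPQ (higher wins) → CIGAR matched
bases (more wins) → mismatch count (fewer wins)**. The comparison order
follows the natural quality direction of each tier; CIGAR strings are
compared through their total M-length so that equivalent alignments with
different operation splits still tie. A read equal on all tiers maps
"commonly"; common reads whose two loci lift to different reference
positions (configurable slack, default 0 bp) are discarded as ambiguous,
and loci that cannot be lifted (inside a haplotype-only insertion) are
discarded as unmappable. Reads aligned to only one haplotype are
exclusive to it ("single-mapping").

Duplicate handling is Picard-like at the granularity the metrics record
affords: reads flagged as duplicates are dropped, and among unflagged
reads sharing both alignment loci only the first seen is kept. Strand
and mate coordinates are not part of the metrics record; when reading
BAM input the aligner's own duplicate flag should be trusted instead.
The mismatch count is taken from the Bowtie 2-style XM tag when present,
falling back to NM.

## Peaks and allelic counting

Peak summits are extended symmetrically (default 250 bp, giving 501-bp
regions, clipped at chromosome ends — slopBed semantics). Peaks from the
reference and both haplotype alignments (pre-lifted) are consolidated by
iterative score-ranked selection: repeatedly keep the highest-scoring
remaining peak and remove everything overlapping it. The result is
non-overlapping and every retained peak is one input peak verbatim.
Scorers that require 500-bp windows receive the region trimmed by 1 bp
at the 3′ end.

Allele counts at het sites inside peaks come from the haplotype-
exclusive read sets only: a read contributes to a haplotype's count iff
it covers the lifted site and carries that haplotype's allele; third
bases (sequencing errors) count for neither. Common-set pileups can be
inspected for QC but are not allele-informative. Coverage filters are
per assay: ≥ 6 reads for ATAC and ChIP, ≥ 10 for RNA (configurable).
Peaks containing several variants with inconsistent allelic direction
are flagged and excluded from motif scoring.

## Imbalance testing

The test is conjugate throughout: WGS counts (#A, #B) give a
Beta(1 + #A, 1 + #B) posterior for the allele fraction (uniform prior,
binomial likelihood), and assay counts are tested two-tailed against the
resulting beta-binomial. The two-sided p-value is defined by
minimum-likelihood mass summation — the sum over outcomes whose
probability does not exceed the observed outcome's, with a relative tie
tolerance of 1e-9 — rather than tail doubling; this is exact, symmetric
for symmetric priors, and never exceeds 1. BH controls FDR across sites.

A deliberate modeling substitution: the published Bayesian framework
this stage corresponds to estimates corrected allelic ratios by MCMC.
Here the same intent — genomic ratios absorb copy number — is realized
deterministically: the corrected allelic ratio divides the observed odds
by the genomic odds (posterior-mean WGS fraction), optionally divided by
a reference-bias odds term (default 0.5, i.e. none, appropriate for
personalized-genome alignments where reference bias is largely
prevented; configurable for reference-aligned inputs). Accessibility,
histone and TF-binding calls require q < 0.05 *and* a corrected ratio
outside the [0.4, 0.6] balance band (the published decision band of
that framework); expression calls use q alone. The band and threshold
are configurable.

Calibration behavior worth knowing: under the model null (assay counts
binomial at the site's genomic ratio) the posterior predictive is wider
than the sampling distribution, so p-values are conservative
(super-uniform) — type-I error ≈ 0.01 at α = 0.05 in the shipped
calibration run. If assay counts are overdispersed relative to the
binomial (the simulator's default dataset mode, ρ_od = 0.02), the test
becomes mildly anti-conservative; the WGS prior absorbs most but not all
of realistic extra-variance. Power at the default study conditions (WGS
depth 40, planted ratio 0.85, assay depth 50, BH over 5,000 sites) is
≈ 0.77 — a useful reference point when choosing depths for a design.

## Copy-number timing and WGD

`mcn = n_tot · VAF / ρ`, rounded half-away-from-zero (the estimate is
immediately discretized into the mcn ≥ 2 / mcn = 1 decision, so the
rounding convention only matters at exact halves), floored at 0 and
capped at the major copy number when a segment is supplied. Timing is
attempted only where pre- and post-gain scenarios are separable:
LOH-with-gain (n_minor = 0, n_major ≥ 2) or gains on both alleles
(n_minor ≥ 2); elsewhere the class is `na`, as is any mcn inconsistent
with its segment. Purity defaults to 1.0 (pure cell lines).

WGD is called when ploidy > c0 − c1 · fraction-of-genome-LOH with
defaults (c0, c1) = (2.9, 2.0). These constants are this package's
substitutes for the commonly used diagonal in the ploidy-LOH plane, not
values asserted by any upstream source; they are exposed as parameters
and the boundary is strict (a sample exactly on it is not called
doubled).

## Motif deltas and enrichment

A sequence's motif score is the best single-site log2-odds over all
windows on both strands (windows containing N score −∞). This is a
deliberate simplification of HMM-based CRM scoring: at a single variant
the best-hit delta preserves the gain/loss signal, is deterministic, and
is checkable against a brute-force oracle; the scorer sits behind an
interface so a multi-site CRM scorer can be plugged in. PWMs take a
0.001-per-cell pseudocount before row normalization; background defaults
to uniform and can be replaced by a 0-order model from control peaks.
Cluster-Buster and JASPAR text formats are read.

The delta score of an allele-specific peak is best-site(preferred
allele) − best-site(other allele), the preferred allele being the one
with the higher assay signal. Per motif, a one-sided Fisher's exact test
compares delta-cutoff exceedance (default |log2-odds| cutoff 3.0; the
cutoff is a config knob with no canonical value) in event vs control
peaks, direction "greater" for gains and "less" for repressor-style
negative associations, BH-corrected across motifs. Odds ratios use a
Haldane 0.5 correction only when a cell is zero.

**Explained fraction at FPR f**: the threshold is the smallest value t
such that at most a fraction f of control scores lie strictly above t
(empirical (1 − f)-quantile, higher-value convention); the explained
fraction is the share of event scores strictly above t. A label-shuffle
baseline repeats this on permuted event/control pools and should average
≈ f.

## Saturation mutagenesis engine

The engine is scorer-agnostic: anything exposing `n_classes`,
`window_length` and `score`/`score_batch` works, including an external
model behind a documented subprocess TSV contract (`seq_id sequence` in,
`seq_id class_0 ... class_k` out), so trained networks can be used
without adding a deep-learning dependency here. For a length-L window,
exactly 3L mutants plus the reference are scored (1,500 mutants at
L = 500) and per-class deltas recorded in an (L × 4 × classes) array
whose reference-base entries are zero by construction. Deltas are
computed on raw class scores in [0, 1], not logits.

For allele pairs at indels, each haplotype's window is re-extracted
around the lifted peak summit rather than substituting into one
backbone, so coordinates stay consistent. The shipped reference scorer
maps each class to `logistic(slope · best-site(seq, PWM_c) + offset)` —
deterministic and closed-form, which lets engine tests verify deltas
exactly; it is a reference implementation of the interface, not an
emulation of any particular trained model.

## Synthetic data

The generator emits a miniature diploid dataset with full ground truth:
reference (default 2 × 500 kb), phased het SNVs (~2 per kb) and sparse
simple indels, an aneuploid segment profile (haplotype 1 always carries
the major allele), 501-bp peaks centered on sampled SNVs, WGS counts
binomial at the copy-number-determined fraction, and assay counts
beta-binomial at a truth ratio that combines the genomic fraction with
any planted regulatory imbalance in odds space (so the corrected ratio
recovers the regulatory component). Het sites are not placed in LOH
segments, where they could not exist in germline. Timing truth uses
CN-consistent VAFs: "early" variants sit on all major copies, "late" on
one. Defaults: planted imbalance 0.85 in 10% of in-peak sites, WGS depth
40 (typical ~38× sequencing), assay depths 30, overdispersion 0.02.

Reads are sampled uniformly from their haplotype of origin and compared
to both haplotypes by exact Hamming distance through the coordinate
maps; there is no aligner, fragment-size model, Tn5 bias, base-quality
structure or mapping error. Consequences: passing the read-assignment
recovery tests shows the classifier logic is exact, not that a real
aligner's MAPQ/XM behavior is handled; passing calibration tests shows
the test matches its model null, while real ATAC data will be additionally
overdispersed (see above). All randomness flows through one seeded
generator; identical configs produce byte-identical output files.

## Numerical conventions

- Beta-binomial masses via log-gamma; enumeration sums clipped at 1.
- Allelic ratios of exactly 0 or 1 are clamped to [1e-6, 1 − 1e-6]
  before odds conversion.
- Tie order in peak consolidation: score desc, then (chrom, start,
  peak_id) — deterministic for equal scores.
- Explained-fraction thresholds use strict ">" on both sides of the
  definition, making the function exact on discrete score sets.
- Problem sizes in the shipped verification runs (5,000 sites for
  calibration and recovery, 10,000 classifier pairs, 1,000 scanner
  cases, 50 + 500 peaks for the planted-gain screen) were chosen as the
  smallest sizes at which the binomial noise on the measured rates is
  well below the margins being asserted.

## Known limitations

- The corrected allelic ratio is a point estimate; no credible interval
  is reported.
- The beta-binomial test has no overdispersion parameter; strongly
  overdispersed assays will inflate type-I error (a Dirichlet-multinomial
  or estimated-ρ extension would be the natural upgrade).
- Best-site motif scoring ignores homotypic site clusters; a CRM-style
  scorer can be plugged into the same interface.
- WGD constants are heuristics; treat the verdict as a flag for review.
- The simulator's alignment metrics are exact string comparisons;
  aligner-specific artifacts (soft-clipping, MAPQ shading) are out of
  scope.
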