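"""Allele-specific event calling with a WGS-informed beta-binomial test.

For each phased het site the WGS allele counts (#A, #B) define a
conjugate posterior Beta(1 + #A, 1 + #B) for the B-allele fraction
(uniform Beta(1, 1) prior, binomial likelihood).  The functional-assay
counts (ATAC, RNA, ChIP) at the same site are then tested against the
resulting beta-binomial: a two-tailed p-value is computed by summing the
mass of every outcome no more likely than the observed one (minimum-
likelihood definition, exact and symmetric for symmetric priors).

Because the WGS counts carry the local copy-number state, imbalance that
is fully explained by copy number is absorbed by the prior.  For the
accessibility and binding assays a second guard is applied: the observed
allelic ratio is corrected in odds space by the genomic ratio, and a
call is made only when the corrected ratio leaves the [0.4, 0.6]
balance band (the published decision band of the Bayesian framework this
model stands in for).  Multiple testing is controlled with
Benjamini–Hochberg FDR; non-significant sites form the control set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln
from statsmodels.stats.multitest import multipletests

from .counting import AlleleCountRecord, Assay

__all__ = [
    "WgsPrior",
    "ImbalanceCall",
    "betabin_pmf",
    "betabin_logpmf",
    "ase_test",
    "corrected_allelic_ratio",
    "bh_fdr",
    "call_events",
    "cross_sample_concordance",
    "EVENT_TYPE_BY_ASSAY",
]

#: Event nomenclature per assay: accessibility (ASCAV), expression
#: (ASEV), histone (ASHV) and TF binding (ASB) variants.
EVENT_TYPE_BY_ASSAY: dict[Assay, str] = {
    Assay.ATAC: "ASCAV",
    Assay.RNA: "ASEV",
    Assay.CHIP_H3K27AC: "ASHV",
    Assay.CHIP_TF: "ASB",
}

#: Assays whose significance additionally requires the corrected ratio
#: to leave the balance band (expression calls use the q-value alone).
_BANDED_ASSAYS = {Assay.ATAC, Assay.CHIP_H3K27AC, Assay.CHIP_TF}

_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class WgsPrior:
    """Beta posterior of the allele fraction from WGS counts.

    alpha = 1 + #A, beta = 1 + #B (uniform prior, binomial likelihood);
    #A counts the same allele as the assay's first count.
    """

    a_count: int
    b_count: int

    def __post_init__(self):
        if self.a_count < 0 or self.b_count < 0:
            raise ValueError("WGS counts must be non-negative")

    @property
    def alpha(self) -> float:
        return 1.0 + self.a_count

    @property
    def beta(self) -> float:
        return 1.0 + self.b_count

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


def betabin_logpmf(k, n: int, alpha: float, beta: float):
    """Log beta-binomial mass, vectorized over k."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    k = np.asarray(k)
    if np.any((k < 0) | (k > n)) or n < 0:
        raise ValueError("require 0 <= k <= n")
    return (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + betaln(k + alpha, n - k + beta) - betaln(alpha, beta)
    )


def betabin_pmf(k, n: int, alpha: float, beta: float):
    """Beta-binomial mass C(n,k) B(k+alpha, n-k+beta) / B(alpha, beta)."""
    return np.exp(betabin_logpmf(k, n, alpha, beta))


def ase_test(assay_a: int, assay_b: int, prior: WgsPrior) -> float:
    """Two-tailed beta-binomial test of assay counts against the WGS prior.

    p is the total mass of outcomes k in 0..n whose likelihood does not
    exceed the observed outcome's (relative tie tolerance 1e-9).
    """
    n = assay_a + assay_b
    if n < 1:
        raise ValueError("zero assay depth")
    logp = betabin_logpmf(np.arange(n + 1), n, prior.alpha, prior.beta)
    obs = logp[assay_a]
    p = float(np.exp(logp[logp <= obs + np.log1p(_TIE_RTOL)]).sum())
    return min(p, 1.0)


def ase_test_batch(a: np.ndarray, b: np.ndarray, wgs_a: np.ndarray, wgs_b: np.ndarray) -> np.ndarray:
    """Vectorized `ase_test` over arrays of assay and WGS counts."""
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    wgs_a = np.asarray(wgs_a, dtype=int)
    wgs_b = np.asarray(wgs_b, dtype=int)
    out = np.empty(a.shape, dtype=float)
    for i in range(a.size):
        out.flat[i] = ase_test(
            int(a.flat[i]), int(b.flat[i]),
            WgsPrior(int(wgs_a.flat[i]), int(wgs_b.flat[i])),
        )
    return out


def corrected_allelic_ratio(
    observed_raf: float, genomic_raf: float, ref_bias: float = 0.5, eps: float = 1e-6
) -> float:
    """Remove the genomic (copy-number) component from an observed ratio.

    Works in odds space: corrected odds = odds(observed) / odds(genomic)
    / odds(ref_bias) (the last factor is 1 for the default unbiased
    setting).  Ratios at exactly 0 or 1 are clamped to [eps, 1 - eps].
    """

    def clamp(x: float) -> float:
        return min(max(x, eps), 1.0 - eps)

    def odds(x: float) -> float:
        x = clamp(x)
        return x / (1.0 - x)

    c = odds(observed_raf) / odds(genomic_raf) / odds(ref_bias)
    return c / (1.0 + c)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class ImbalanceCall:
    record: AlleleCountRecord
    p_value: float
    q_value: float
    observed_raf: float
    corrected_raf: float
    significant: bool
    event_type: str

    @property
    def preferred_haplotype(self) -> int:
        """Haplotype with the higher assay signal (1 or 2)."""
        return 1 if self.record.hap1_count >= self.record.hap2_count else 2


def call_events(
    records: Sequence[AlleleCountRecord],
    fdr_threshold: float = 0.05,
    balance_band: tuple[float, float] = (0.4, 0.6),
    ref_bias: float = 0.5,
) -> tuple[list[ImbalanceCall], list[ImbalanceCall]]:
    """Test every record and split calls into (significant, control).

    Expression records are significant at q < fdr_threshold; the banded
    assays additionally require corrected_raf outside balance_band.
    Records should already have passed the per-assay coverage filter.
    """
    if not records:
        return [], []
    p = np.array([
        ase_test(r.hap1_count, r.hap2_count, WgsPrior(r.wgs_a, r.wgs_b)) for r in records
    ])
    q = bh_fdr(p)
    lo, hi = balance_band
    sig_calls: list[ImbalanceCall] = []
    controls: list[ImbalanceCall] = []
    for r, pi, qi in zip(records, p, q):
        obs = r.hap1_count / r.depth
        prior = WgsPrior(r.wgs_a, r.wgs_b)
        corr = corrected_allelic_ratio(obs, prior.mean, ref_bias=ref_bias)
        sig = qi < fdr_threshold
        if r.assay in _BANDED_ASSAYS:
            sig = sig and not (lo <= corr <= hi)
        call = ImbalanceCall(
            record=r, p_value=float(pi), q_value=float(qi),
            observed_raf=obs, corrected_raf=corr, significant=bool(sig),
            event_type=EVENT_TYPE_BY_ASSAY[r.assay],
        )
        (sig_calls if sig else controls).append(call)
    return sig_calls, controls


def cross_sample_concordance(
    calls_by_sample: Mapping[str, Iterable[ImbalanceCall]],
) -> pd.DataFrame:
    """Direction agreement of events shared between samples.

    Variants significant in at least two samples are reported with the
    favored haplotype per sample and a concordance flag; variants
    significant in a single sample only are excluded.
    """
    rows = []
    for sample, calls in calls_by_sample.items():
        for c in calls:
            if not c.significant:
                continue
            v = c.record.variant
            rows.append(
                {
                    "chrom": v.chrom, "pos": v.pos, "ref": v.ref_allele,
                    "alt": v.alt_allele, "sample": sample,
                    "preferred_haplotype": c.preferred_haplotype,
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "n_samples", "samples", "concordant"]
        )
    df = pd.DataFrame(rows)
    out = []
    for key, grp in df.groupby(["chrom", "pos", "ref", "alt"], sort=True):
        if len(grp) < 2:
            continue
        out.append(
            {
                "chrom": key[0], "pos": key[1], "ref": key[2], "alt": key[3],
                "n_samples": len(grp),
                "samples": ",".join(sorted(grp["sample"])),
                "concordant": grp["preferred_haplotype"].nunique() == 1,
            }
        )
    return pd.DataFrame(out, columns=["chrom", "pos", "ref", "alt", "n_samples", "samples", "concordant"])


def calls_to_frame(calls: Iterable[ImbalanceCall]) -> pd.DataFrame:
    """Flatten calls into the output table written by the CLI."""
    rows = []
    for c in calls:
        r, v = c.record, c.record.variant
        rows.append(
            {
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref_allele, "alt": v.alt_allele,
                "assay": r.assay.value, "hap1_count": r.hap1_count, "hap2_count": r.hap2_count,
                "wgs_a": r.wgs_a, "wgs_b": r.wgs_b, "peak_id": r.peak_id,
                "p": c.p_value, "q": c.q_value,
                "observed_raf": c.observed_raf, "corrected_raf": c.corrected_raf,
                "significant": c.significant, "event_type": c.event_type,
            }
        )
    return pd.DataFrame(rows)
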