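"""WGS-prior beta-binomial testing, ratio correction, FDR and calling."""

import math
from fractions import Fraction

import numpy as np
import pytest

from ascav.counting import AlleleCountRecord, Assay
from ascav.genome import PhasedVariant
from ascav.simulate import simulate_null_counts
from ascav.stats import (
    ImbalanceCall,
    WgsPrior,
    ase_test,
    betabin_logpmf,
    betabin_pmf,
    bh_fdr,
    call_events,
    corrected_allelic_ratio,
    cross_sample_concordance,
)

TIE = Fraction(10**9 + 1, 10**9)  # the test's (1 + 1e-9) tie tolerance


def exact_pmf(k: int, n: int, a: int, b: int) -> Fraction:
    """Exact rational beta-binomial mass for integer shape parameters,
    via factorial products (independent of the log-Beta implementation)."""
    f = math.factorial
    return (
        Fraction(math.comb(n, k))
        * Fraction(f(k + a - 1) * f(n - k + b - 1) * f(a + b - 1),
                   f(a - 1) * f(b - 1) * f(n + a + b - 1))
    )


def oracle_p(k_obs: int, n: int, a: int, b: int) -> float:
    """Full-enumeration two-sided minimum-likelihood p in exact rationals."""
    pmf = [exact_pmf(k, n, a, b) for k in range(n + 1)]
    thresh = pmf[k_obs] * TIE
    return float(sum(p for p in pmf if p <= thresh))


class TestBetabinPmf:
    def test_uniform_case(self):
        assert betabin_pmf(0, 1, 1, 1) == pytest.approx(0.5)

    def test_normalization(self):
        total = betabin_pmf(np.arange(21), 20, 31, 11).sum()
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_dual_formula_agreement(self):
        got = betabin_pmf(10, 20, 2, 2)
        assert got == pytest.approx(float(exact_pmf(10, 20, 2, 2)), abs=1e-12)

    def test_invalid_ranges(self):
        with pytest.raises(ValueError):
            betabin_pmf(5, 4, 1, 1)
        with pytest.raises(ValueError):
            betabin_logpmf(0, 4, 0, 1)


class TestAseTest:
    def test_observation_at_mode_is_one(self):
        assert ase_test(5, 5, WgsPrior(10, 10)) == pytest.approx(1.0)

    def test_matches_enumeration_example(self):
        # WGS 30/10 -> prior Beta(31, 11); RNA 20/0
        assert ase_test(20, 0, WgsPrior(30, 10)) == pytest.approx(
            oracle_p(20, 20, 31, 11), abs=1e-12
        )

    def test_relabeling_symmetry(self):
        assert ase_test(3, 12, WgsPrior(8, 25)) == pytest.approx(
            ase_test(12, 3, WgsPrior(25, 8)), abs=1e-15
        )

    def test_zero_depth_errors(self):
        with pytest.raises(ValueError):
            ase_test(0, 0, WgsPrior(5, 5))

    def test_monotone_in_distance_from_posterior_mean(self):
        """p never increases as the count moves away from the prior mean."""
        prior = WgsPrior(20, 20)
        n = 30
        ps = [ase_test(k, n - k, prior) for k in range(n + 1)]
        center = int(round(prior.mean * n))
        assert all(ps[k] >= ps[k + 1] - 1e-12 for k in range(center, n))
        assert all(ps[k] >= ps[k - 1] - 1e-12 for k in range(1, center + 1))

    def test_enumeration_oracle_small_grid(self):
        """Spot grid here; the exhaustive n <= 60 sweep runs in acceptance."""
        for a, b in [(1, 1), (11, 11), (31, 11), (5, 45)]:
            for n in (1, 7, 23):
                for k in range(0, n + 1, max(1, n // 4)):
                    assert ase_test(k, n - k, WgsPrior(a - 1, b - 1)) == pytest.approx(
                        oracle_p(k, n, a, b), abs=1e-12
                    )


class TestCorrectedRatio:
    @pytest.mark.parametrize(
        "obs, gen, expected",
        [(0.75, 0.5, 0.75), (0.75, 0.75, 0.5), (0.9, 0.75, 0.75)],
    )
    def test_odds_space_correction(self, obs, gen, expected):
        assert corrected_allelic_ratio(obs, gen) == pytest.approx(expected)

    def test_extreme_ratios_clamped(self):
        out = corrected_allelic_ratio(1.0, 0.5)
        assert 0 < out < 1

    def test_ref_bias_factor(self):
        # with ref_bias equal to the observation, correction is neutralized
        assert corrected_allelic_ratio(0.75, 0.5, ref_bias=0.75) == pytest.approx(0.5)


class TestCorrectedRatioProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    ratios = st.floats(min_value=0.01, max_value=0.99)

    @given(obs=ratios)
    @settings(deadline=None, derandomize=True)
    def test_balanced_genome_is_identity(self, obs):
        assert corrected_allelic_ratio(obs, 0.5) == pytest.approx(obs, abs=1e-9)

    @given(obs=ratios, gen=ratios)
    @settings(deadline=None, derandomize=True)
    def test_allele_relabeling_antisymmetry(self, obs, gen):
        """Swapping which allele is 'A' mirrors the corrected ratio."""
        c = corrected_allelic_ratio(obs, gen)
        c_swapped = corrected_allelic_ratio(1 - obs, 1 - gen)
        assert c_swapped == pytest.approx(1 - c, abs=1e-9)

    @given(obs=ratios, gen=ratios)
    @settings(deadline=None, derandomize=True)
    def test_output_in_unit_interval(self, obs, gen):
        assert 0.0 < corrected_allelic_ratio(obs, gen) < 1.0


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.04]) == pytest.approx([0.04])

    def test_step_up_by_hand(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)


class TestCallEvents:
    def rec(self, pos, a, b, wa, wb, assay=Assay.ATAC):
        v = PhasedVariant("chr1", pos, "A", "C", (1, 0))
        return AlleleCountRecord(v, assay, a, b, wa, wb, peak_id=f"p{pos}")

    def test_strong_imbalance_called(self):
        recs = [self.rec(1, 28, 2, 20, 20)] + [self.rec(i, 15, 15, 20, 20) for i in range(2, 30)]
        sig, ctrl = call_events(recs)
        assert len(sig) == 1 and sig[0].record.variant.pos == 1
        assert sig[0].event_type == "ASCAV"
        assert sig[0].corrected_raf > 0.6

    def test_copy_number_explained_not_called(self):
        """Strong imbalance matching the genomic ratio is not an event."""
        recs = [self.rec(1, 27, 3, 36, 4)] + [self.rec(i, 15, 15, 20, 20) for i in range(2, 30)]
        sig, _ = call_events(recs)
        assert sig == []

    def test_expression_calls_skip_balance_band(self):
        # significant q with corrected ratio inside the band: RNA still calls
        recs = [self.rec(1, 34, 4, 20, 20, Assay.RNA)] + [
            self.rec(i, 15, 15, 20, 20, Assay.RNA) for i in range(2, 30)
        ]
        sig, _ = call_events(recs, balance_band=(0.01, 0.99))
        assert len(sig) == 1 and sig[0].event_type == "ASEV"

    def test_null_call_rate_bounded(self):
        """Null run: significant fraction stays within 1.5x the nominal FDR."""
        recs = simulate_null_counts(5000, 40, 30, rng=np.random.default_rng(21))
        sig, _ = call_events(recs)
        assert len(sig) / 5000 <= 1.5 * 0.05


class TestConcordance:
    def call(self, pos, c1, c2, sig=True):
        v = PhasedVariant("chr1", pos, "A", "C", (1, 0))
        r = AlleleCountRecord(v, Assay.ATAC, c1, c2, 20, 20, peak_id="p")
        return ImbalanceCall(r, 0.001, 0.01, c1 / (c1 + c2), c1 / (c1 + c2), sig, "ASCAV")

    def test_same_direction_concordant(self):
        df = cross_sample_concordance({"s1": [self.call(1, 20, 2)], "s2": [self.call(1, 18, 3)]})
        assert len(df) == 1 and bool(df.concordant.iloc[0])

    def test_opposite_direction_discordant(self):
        df = cross_sample_concordance({"s1": [self.call(1, 20, 2)], "s2": [self.call(1, 3, 18)]})
        assert len(df) == 1 and not bool(df.concordant.iloc[0])

    def test_singleton_excluded(self):
        df = cross_sample_concordance({"s1": [self.call(1, 20, 2)], "s2": [self.call(2, 20, 2)]})
        assert df.empty
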