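"""PWM scanning, delta scores, enrichment and explained-fraction curves."""

import math

import numpy as np
import pytest

from ascav.motifs import (
    PWM,
    best_site_score,
    delta_motif_score,
    enrich_motifs,
    enrichment_test,
    explained_fraction_at_fpr,
    label_shuffle_baseline,
    read_pwms,
    write_pwm_cb,
)

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(COMP)[::-1]


def oracle_best_site(seq: str, pwm: PWM) -> float:
    """Brute-force all-window two-strand scan in plain Python."""
    lo = pwm.log_odds
    best = -math.inf
    for strand_seq in (seq, revcomp(seq)):
        for i in range(len(strand_seq) - len(pwm) + 1):
            window = strand_seq[i : i + len(pwm)]
            if any(b not in "ACGT" for b in window):
                continue
            s = sum(lo[j, "ACGT".index(b)] for j, b in enumerate(window))
            best = max(best, s)
    return best


def random_pwm(rng, motif_id="m", length=None):
    length = length or int(rng.integers(4, 12))
    return PWM(motif_id, rng.dirichlet(np.ones(4) * 0.5, size=length))


class TestBestSiteScore:
    def test_consensus_scores_motif_length(self, toy_pwm):
        assert best_site_score("AAACGTAA", toy_pwm) == pytest.approx(4.0)

    def test_reverse_strand_hit(self, toy_pwm_aacg):
        # TTCGTTTT contains CGTT = revcomp(AACG)
        assert best_site_score("TTCGTTTT", toy_pwm_aacg) == pytest.approx(4.0)

    def test_all_n_sequence_is_minus_inf(self, toy_pwm):
        assert best_site_score("NNNNNNNN", toy_pwm) == -math.inf

    def test_sequence_shorter_than_motif_errors(self, toy_pwm):
        with pytest.raises(ValueError, match="shorter"):
            best_site_score("ACG", toy_pwm)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(77)
        bases = np.array(list("ACGTN"))
        for i in range(300):
            pwm = random_pwm(rng, f"m{i}")
            n = int(rng.integers(len(pwm), 60))
            seq = "".join(rng.choice(bases, n, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            got = best_site_score(seq, pwm)
            want = oracle_best_site(seq, pwm)
            if math.isinf(want):
                assert math.isinf(got)
            else:
                assert got == pytest.approx(want, abs=1e-9)


class TestScannerProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    seqs = st.text(alphabet="ACGT", min_size=8, max_size=40)

    @given(seq=seqs)
    @settings(deadline=None, derandomize=True)
    def test_reverse_complement_invariance(self, seq, toy_pwm):
        """Two-strand scanning makes the score strand-agnostic."""
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert best_site_score(seq, toy_pwm) == pytest.approx(
            best_site_score(rc, toy_pwm), abs=1e-9
        )

    @given(seq=seqs)
    @settings(deadline=None, derandomize=True)
    def test_delta_zero_on_identity(self, seq, toy_pwm):
        assert delta_motif_score(seq, seq, toy_pwm).delta == 0.0


class TestDeltaScore:
    def test_identical_sequences_zero(self, toy_pwm):
        d = delta_motif_score("AAACGTAA", "AAACGTAA", toy_pwm)
        assert d.delta == 0.0

    def test_single_disruption_delta(self, toy_pwm):
        # preferred completes ACGT (score 4); other carries ACTT: best window
        # scores 2 (three matches, one mismatch)
        d = delta_motif_score("AAACGTAA", "AAACTTAA", toy_pwm)
        assert d.delta == pytest.approx(4.0 - 2.0)

    def test_antisymmetry(self, toy_pwm):
        a, b = "AAACGTAA", "AAACTTAA"
        d1 = delta_motif_score(a, b, toy_pwm)
        d2 = delta_motif_score(b, a, toy_pwm)
        assert d1.delta == pytest.approx(-d2.delta)


def oracle_fisher_greater(a, b, c, d):
    """One-sided hypergeometric tail by direct summation."""
    n, K, N = a + b, a + c, a + b + c + d

    def hyper(x):
        return math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)

    return sum(hyper(x) for x in range(a, min(n, K) + 1))


class TestEnrichment:
    def test_closed_form_odds_ratio_and_p(self):
        # 30/100 events above vs 50/900 controls above
        ev = [4.0] * 30 + [0.0] * 70
        ct = [4.0] * 50 + [0.0] * 850
        r = enrichment_test(ev, ct, "m", threshold=3.0)
        assert r.odds_ratio == pytest.approx((30 * 850) / (70 * 50))
        assert r.p_value == pytest.approx(oracle_fisher_greater(30, 70, 50, 850), rel=1e-9)

    def test_identical_distributions_null(self):
        # literally the same score multiset on both sides: OR = 1, p >= 0.5
        pool = list(np.random.default_rng(5).normal(0, 2, 400))
        r = enrichment_test(pool, pool, threshold=3.0)
        assert r.p_value >= 0.5
        assert r.odds_ratio == pytest.approx(1.0)

    def test_all_zero_deltas_degenerate(self):
        r = enrichment_test([0.0] * 50, [0.0] * 500, threshold=3.0)
        assert r.p_value == pytest.approx(1.0)

    def test_loss_direction_counts_negative_deltas(self):
        ev = [-4.0] * 30 + [0.0] * 70
        ct = [0.0] * 900
        r = enrichment_test(ev, ct, threshold=3.0, direction="less")
        assert r.event_above == 30 and r.p_value < 1e-6

    def test_margins_preserved(self):
        r = enrichment_test([5, 0, 0], [5, 5, 0, 0], threshold=3.0)
        assert r.event_above + r.event_below == 3
        assert r.control_above + r.control_below == 4


class TestExplainedFraction:
    def test_perfect_separation(self):
        t, f = explained_fraction_at_fpr([1.0] * 10, [0.0] * 100, fpr=0.05)
        assert f == 1.0

    def test_quantile_convention(self):
        controls = list(range(1, 101))
        t, f = explained_fraction_at_fpr([10, 96, 99], controls, fpr=0.05)
        assert t == 95
        assert f == pytest.approx(2 / 3)

    def test_null_events_give_fpr(self):
        rng = np.random.default_rng(31)
        ct = rng.normal(0, 1, 4000)
        ev = rng.normal(0, 1, 2000)
        _, f = explained_fraction_at_fpr(ev, ct, fpr=0.05)
        se = math.sqrt(0.05 * 0.95 / 2000)
        assert abs(f - 0.05) < 4 * se

    def test_invalid_fpr(self):
        with pytest.raises(ValueError):
            explained_fraction_at_fpr([1], [1], fpr=0.0)


class TestShuffleBaseline:
    def test_fractions_in_unit_interval(self):
        rng = np.random.default_rng(1)
        f = label_shuffle_baseline(rng.normal(2, 1, 50), rng.normal(0, 1, 500), n_perm=20)
        assert np.all((0 <= f) & (f <= 1))

    def test_mean_near_fpr_for_pooled_identical(self):
        rng = np.random.default_rng(2)
        pool = rng.normal(0, 1, 1000)
        f = label_shuffle_baseline(pool[:200], pool[200:], fpr=0.05, n_perm=200, seed=3)
        se = math.sqrt(0.05 * 0.95 / 200) / math.sqrt(200)
        # permutation fractions are correlated; allow a generous factor
        assert abs(f.mean() - 0.05) < 0.02

    def test_seeded_reproducibility(self):
        ev, ct = [1.0, 2.0, 3.0], list(np.linspace(0, 4, 50))
        f1 = label_shuffle_baseline(ev, ct, n_perm=1, seed=11)
        f2 = label_shuffle_baseline(ev, ct, n_perm=1, seed=11)
        assert np.array_equal(f1, f2)


class TestPlantedGainEndToEnd:
    def test_planted_pwm_flagged_no_decoy_passes(self, toy_pwm):
        """A motif gain planted in event peaks (absent from controls) is the
        only motif flagged by the Fisher screen."""
        from ascav.simulate import plant_motif_gain

        rng = np.random.default_rng(55)
        bases = np.array(list("ACGT"))
        decoys = []
        for i in range(20):
            cons = rng.dirichlet(np.ones(4) * 0.3, size=8)
            decoys.append(PWM(f"decoy_{i}", cons))
        pwms = [toy_pwm] + decoys

        def rand_seq(n):
            return "".join(rng.choice(bases, n))

        ev_deltas = {p.motif_id: [] for p in pwms}
        ct_deltas = {p.motif_id: [] for p in pwms}
        for _ in range(50):
            planted = plant_motif_gain(rand_seq(200), toy_pwm, position=80)
            for p in pwms:
                d = best_site_score(planted.hap1_seq, p) - best_site_score(planted.hap2_seq, p)
                ev_deltas[p.motif_id].append(d)
        for _ in range(500):
            seq = rand_seq(200)
            pos = int(rng.integers(0, 200))
            alt = str(rng.choice([b for b in "ACGT" if b != seq[pos]]))
            other = seq[:pos] + alt + seq[pos + 1 :]
            for p in pwms:
                ct_deltas[p.motif_id].append(
                    best_site_score(seq, p) - best_site_score(other, p)
                )
        results = {r.motif_id: r for r in enrich_motifs(ev_deltas, ct_deltas, threshold=1.5)}
        assert results["toy_acgt"].p_value < 1e-3
        assert all(r.q_value >= 0.05 for m, r in results.items() if m != "toy_acgt")


class TestPwmIO:
    def test_cb_roundtrip(self, tmp_path):
        rng = np.random.default_rng(4)
        pwms = [random_pwm(rng, f"mot_{i}") for i in range(3)]
        path = tmp_path / "motifs.cb"
        write_pwm_cb(pwms, path)
        back = read_pwms(path)
        assert [p.motif_id for p in back] == [p.motif_id for p in pwms]
        for a, b in zip(back, pwms):
            # re-reading applies the pseudocount to already-normalized rows,
            # shifting entries by up to ~pseudocount/(1 + 4*pseudocount)
            np.testing.assert_allclose(a.matrix, b.matrix, atol=5e-3)

    def test_jaspar_format(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(
            ">MA0001.1 TEST\n"
            "A [ 10  0  5 ]\n"
            "C [  0 10  5 ]\n"
            "G [  0  0  0 ]\n"
            "T [  0  0  0 ]\n"
        )
        [pwm] = read_pwms(path)
        assert len(pwm) == 3
        assert pwm.consensus == "ACA" or pwm.consensus[:2] == "AC"
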