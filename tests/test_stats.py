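"""Permutation run-length statistics, jackknife onsets, JZS Bayes factors."""

import math
import warnings

import numpy as np
import pytest

from dispvep import stats as dstats
from dispvep.synth import pink_noise

FS = 420.0


def smooth_null(n_subj, n_time, rng):
    return pink_noise(n_time, rng, 1.0, size=(n_subj,))


class TestPointwisePairedT:
    def test_identical_conditions_give_t0_p1(self, rng):
        a = rng.standard_normal((6, 50))
        t, p = dstats.pointwise_paired_t(a, a.copy())
        assert np.allclose(t, 0.0)
        assert np.allclose(p, 1.0)

    def test_hand_computed_three_subject_example(self):
        a = np.array([[1.0], [2.0], [3.0]])
        b = np.zeros((3, 1))
        t, _ = dstats.pointwise_paired_t(a, b)
        assert t[0] == pytest.approx(2.0 / (1.0 / math.sqrt(3)), abs=1e-12)

    def test_matches_scipy_ttest_rel(self, rng):
        from scipy.stats import ttest_rel

        a = rng.standard_normal((20, 30))
        b = rng.standard_normal((20, 30))
        t, p = dstats.pointwise_paired_t(a, b)
        ref = ttest_rel(a, b, axis=0)
        assert np.allclose(t, ref.statistic, atol=1e-10)
        assert np.allclose(p, ref.pvalue, atol=1e-10)
        assert ref.df[0] == 19  # 20 subjects -> df 19

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            dstats.pointwise_paired_t(rng.standard_normal((2, 5)),
                                      rng.standard_normal((2, 5)))


class TestRunHelpers:
    def test_longest_run_counts(self):
        flags = np.array([[0, 1, 1, 1, 0, 1], [0, 0, 0, 0, 0, 0]], dtype=bool)
        assert dstats.longest_run(flags).tolist() == [3, 0]

    def test_significant_runs_strict_threshold(self):
        flags = np.array([1, 1, 1, 0, 1, 1], dtype=bool)
        assert dstats.significant_runs(flags, 2) == [(0, 3)]
        assert dstats.significant_runs(flags, 3) == []


class TestPermutationRunlength:
    def test_deterministic_given_seed(self, rng):
        a = smooth_null(10, 100, rng)
        b = smooth_null(10, 100, rng)
        r1 = dstats.permutation_runlength_test(a, b, n_perm=200, seed=5)
        r2 = dstats.permutation_runlength_test(a, b, n_perm=200, seed=5)
        assert r1.run_threshold == r2.run_threshold
        assert r1.segments == r2.segments
        assert np.array_equal(r1.null_runs, r2.null_runs)

    def test_global_label_swap_flips_t_keeps_segments(self, rng):
        a = smooth_null(10, 100, rng) + 0.5
        b = smooth_null(10, 100, rng)
        r_ab = dstats.permutation_runlength_test(a, b, n_perm=200, seed=3)
        r_ba = dstats.permutation_runlength_test(b, a, n_perm=200, seed=3)
        assert np.allclose(r_ab.t, -r_ba.t, atol=1e-12)
        assert r_ab.segments == r_ba.segments

    def test_identical_conditions_no_segments(self, rng):
        a = smooth_null(10, 100, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = dstats.permutation_runlength_test(a, a.copy(), n_perm=200, seed=1)
        assert res.segments == []

    def test_planted_segment_covered_within_3_samples(self, rng):
        # effect is large against the pointwise t (t ~ sqrt(n) * effect/sd)
        # but comparable to the per-subject noise, so unbalanced sign-flip
        # permutations do not contaminate the null run-length distribution
        n_subj, n_time = 20, 300
        a = smooth_null(n_subj, n_time, rng) * 0.1
        b = smooth_null(n_subj, n_time, rng) * 0.1
        lo, hi = 63, 147  # 150-350 ms at 420 Hz
        a[:, lo:hi] += 0.15
        res = dstats.permutation_runlength_test(a, b, n_perm=300, seed=2,
                                                sampling_rate=FS)
        assert len(res.segments) == 1
        s, e = res.segments[0]
        assert abs(s - lo) <= 3
        assert abs(e - hi) <= 3

    def test_low_permutation_count_rejected(self, rng):
        a = smooth_null(5, 20, rng)
        with pytest.raises(ValueError):
            dstats.permutation_runlength_test(a, a, n_perm=50)


class TestJackknifeOnsets:
    def test_degenerate_identical_subjects_give_zero_width(self):
        # every subject carries the same effect waveform; each leave-one-out
        # iteration must time the onset at exactly the planted sample.
        # n = 19 keeps the leave-one-out size at 18, where unbalanced
        # sign-flip permutations stay below the pointwise t criterion.
        onset_sample = 40
        n_subj, n_time = 19, 120
        d = np.zeros(n_time)
        d[onset_sample:80] = 1.0
        base = smooth_null(n_subj, n_time, np.random.default_rng(1)) * 0.01
        a = base + d
        b = base - d
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = dstats.jackknife_onsets(a, b, n_perm=1000, seed=0, sampling_rate=FS)
        expected_ms = onset_sample * 1000.0 / FS
        assert np.allclose(est.onsets_ms, expected_ms, atol=1e-9)
        assert est.ci_se_ms[0] == pytest.approx(est.ci_se_ms[1], abs=1e-6)
        assert est.n_failed == 0

    def test_no_effect_raises(self, rng):
        a = smooth_null(8, 100, rng)
        b = smooth_null(8, 100, rng)
        with pytest.raises(RuntimeError, match="no significant"):
            dstats.jackknife_onsets(a, b, n_perm=200, seed=0, sampling_rate=FS)

    def test_too_few_subjects_rejected(self, rng):
        a = smooth_null(4, 50, rng)
        with pytest.raises(ValueError):
            dstats.jackknife_onsets(a, a, n_perm=200)


class TestCompareOnsets:
    @staticmethod
    def _estimate(values):
        values = np.asarray(values, dtype=float)
        return dstats.OnsetEstimate(
            onsets_ms=values, median_ms=float(np.median(values)),
            ci_se_ms=(0.0, 0.0), ci_percentile_ms=(0.0, 0.0),
        )

    def test_identical_distributions_give_t0_p1(self):
        est = self._estimate([150, 152, 149, 151, 150, 148])
        t, df, p, bf = dstats.compare_onsets(est, est)
        assert t == 0.0 and p == 1.0
        assert df == 5
        assert bf.bf10 < 1.0

    def test_df_is_n_minus_1(self, rng):
        a = self._estimate(150 + rng.standard_normal(20))
        b = self._estimate(160 + rng.standard_normal(20))
        t, df, p, _ = dstats.compare_onsets(a, b)
        assert df == 19
        assert p < 0.001

    def test_miller_ulrich_correction_shrinks_t(self, rng):
        a = self._estimate(150 + rng.standard_normal(10))
        b = self._estimate(155 + rng.standard_normal(10))
        t_naive, *_ = dstats.compare_onsets(a, b)
        t_corr, *_ = dstats.compare_onsets(a, b, corrected=True)
        assert abs(t_corr) == pytest.approx(abs(t_naive) / 9)

    def test_mismatched_n_rejected(self):
        with pytest.raises(ValueError):
            dstats.compare_onsets(self._estimate([1, 2, 3]),
                                  self._estimate([1, 2, 3, 4]))


class TestBayesFactor:
    def test_null_t_favors_h0_for_various_n(self):
        for n in (2, 5, 20, 100):
            assert dstats.bayes_factor_paired_t(0.0, n).bf10 < 1.0

    def test_strictly_monotone_in_abs_t(self):
        grid = np.linspace(0.0, 10.0, 21)
        bfs = [dstats.bayes_factor_paired_t(t, 20).bf10 for t in grid]
        assert np.all(np.diff(bfs) > 0)
        assert dstats.bayes_factor_paired_t(-3.0, 20).bf10 == pytest.approx(
            dstats.bayes_factor_paired_t(3.0, 20).bf10, rel=1e-6
        )

    def test_agrees_with_pingouin_oracle(self):
        pg = pytest.importorskip("pingouin")
        for t, n in [(0.5, 10), (2.0, 20), (4.0, 15), (15.44, 20)]:
            ours = dstats.bayes_factor_paired_t(t, n).bf10
            ref = float(pg.bayesfactor_ttest(t, n, paired=True, r=math.sqrt(2) / 2))
            assert ours == pytest.approx(ref, rel=1e-4)

    def test_large_t_reaches_published_order_of_magnitude(self):
        bf = dstats.bayes_factor_paired_t(15.44, 20).bf10
        assert abs(math.log10(bf) - math.log10(2.25e9)) < 1.0

    def test_nonfinite_t_rejected(self):
        with pytest.raises(ValueError):
            dstats.bayes_factor_paired_t(math.inf, 20)

    def test_windowed_mean_bf(self):
        t_values = np.zeros(300)
        t_values[100:150] = 6.0
        res = dstats.windowed_mean_bf(t_values, 20, (238.1, 354.8), FS)
        single = dstats.bayes_factor_paired_t(6.0, 20).bf10
        assert res.bf10 == pytest.approx(single, rel=1e-6)
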