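"""Daily histograms, CC trajectories, logistic fits, and derived statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from songdev.datamodel import OntogenyDataset, Phase
from songdev.development import (DailyHistogram, DevelopmentFit,
                                 SimilarityTrajectory, cc_trajectory,
                                 cross_treatment_similarity, daily_histograms,
                                 deterioration, dmax, fit_development_curve,
                                 logistic, pearson_cc, recovery,
                                 reference_pattern, stabilization_day)

from conftest import make_calendar, make_records


def hist(counts, feature="SR", day=0, bw=1.0, lo=0):
    counts = np.asarray(counts, float)
    return DailyHistogram(feature=feature, day=day, bin_width=bw,
                          support=(lo, lo + len(counts) - 1), counts=counts)


def _frame(values, day=0, feature_col="syllable_rate_hz"):
    return pd.DataFrame({"experiment_day": day, feature_col: values})


class TestDailyHistogram:
    def test_values_round_to_nearest_integer_bin(self):
        h = daily_histograms(_frame([10.2, 11.6, 9.7]), "SR", 1.0)[0]
        assert h.support == (10, 12)
        np.testing.assert_array_equal(h.counts, [2, 0, 1])

    def test_bin_width_rescales_like_the_values(self):
        # binning v at width w == binning v/w at width 1
        vals = np.array([3.2, 4.9, 8.1, -2.4])
        h1 = daily_histograms(_frame(vals), "SR", 0.5, support=(-10, 20))[0]
        h2 = daily_histograms(_frame(vals / 0.5), "SR", 1.0,
                              support=(-10, 20))[0]
        np.testing.assert_array_equal(h1.counts, h2.counts)

    def test_half_away_from_zero_for_negative_values(self):
        # Wiener entropy is negative; -1.26 at bin width 0.1 -> bin -13
        h = daily_histograms(_frame([-1.26], feature_col="wiener_entropy"),
                             "E", 0.1)[0]
        assert h.support == (-13, -13)

    @pytest.mark.parametrize("seed", range(3))
    def test_large_sample_matches_tally_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(12.0, 4.0, size=100_000)
        h = daily_histograms(_frame(vals), "SR", 1.0)[0]
        oracle = {}
        for v in vals:
            b = int(math.copysign(math.floor(abs(v) + 0.5), v))
            oracle[b] = oracle.get(b, 0) + 1
        lo, hi = h.support
        for b, c in zip(range(lo, hi + 1), h.counts):
            assert oracle.get(b, 0) == c

    def test_requested_day_without_records_is_empty(self):
        hists = daily_histograms(_frame([10.0], day=1), "SR", 1.0,
                                 days=[1, 2])
        assert not hists[1].empty
        assert hists[2].empty


class TestReferencePattern:
    def test_seven_identical_histograms_are_idempotent(self):
        hs = [hist([2, 0, 2], day=d) for d in range(7)]
        ref = reference_pattern(hs)
        np.testing.assert_allclose(ref.counts, hs[0].frequencies)

    def test_weighted_mean_of_frequencies(self):
        a, b = hist([4, 0, 0]), hist([0, 0, 9])
        ref = reference_pattern([a] * 6 + [b])
        np.testing.assert_allclose(
            ref.counts, (6 * a.frequencies + b.frequencies) / 7)

    def test_random_window_matches_mean_oracle(self):
        rng = np.random.default_rng(0)
        hs = [hist(rng.integers(0, 50, size=12), day=d) for d in range(7)]
        ref = reference_pattern(hs)
        oracle = np.mean([h.frequencies for h in hs], axis=0)
        np.testing.assert_allclose(ref.counts, oracle / oracle.sum())

    def test_wrong_window_length_instructs_config(self):
        with pytest.raises(ValueError, match="shorter window"):
            reference_pattern([hist([1, 2])] * 5)


class TestPearsonCC:
    def test_identical_histograms_give_one(self):
        assert pearson_cc(hist([2, 0, 2]), hist([2, 0, 2])) == 1.0

    def test_counts_vs_frequencies_scale_invariance(self):
        assert pearson_cc(hist([2, 0, 2]),
                          hist([0.5, 0.0, 0.5])) == pytest.approx(1.0)

    def test_inverse_pattern_gives_minus_one(self):
        assert pearson_cc(hist([1, 0]), hist([0, 1])) == pytest.approx(-1.0)

    def test_zero_variance_is_missing_not_zero(self):
        assert math.isnan(pearson_cc(hist([3, 3, 3]), hist([1, 2, 3])))

    @pytest.mark.parametrize("seed", range(3))
    def test_positive_affine_rescaling_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 40, size=15).astype(float)
        b = rng.integers(0, 40, size=15).astype(float)
        base = pearson_cc(hist(a), hist(b))
        scaled = pearson_cc(hist(3.7 * a + 2.0), hist(0.2 * b + 9.0))
        assert scaled == pytest.approx(base, abs=1e-12)


class TestCCTrajectory:
    def test_identical_days_give_constant_one(self):
        hs = {d: hist([1, 2, 3], day=d) for d in range(10)}
        ref = reference_pattern([hs[d] for d in range(7)])
        traj = cc_trajectory(hs, ref)
        np.testing.assert_allclose(traj.cc, 1.0)
        assert len(traj.days) == 10

    def test_simulated_drift_is_monotone(self):
        rng = np.random.default_rng(5)
        target = np.exp(-0.5 * ((np.arange(30) - 20) / 3.0) ** 2)
        start = np.exp(-0.5 * ((np.arange(30) - 8) / 3.0) ** 2)
        hs = {}
        for d in range(60):
            w = 1.0 / (1.0 + np.exp((30 - d) / 6.0))
            mix = (1 - w) * start + w * target + rng.normal(0, 1e-3, 30)
            hs[d] = hist(np.clip(mix, 0, None), day=d)
        ref = hist(target)
        traj = cc_trajectory(hs, ref)
        rho = spearmanr(traj.days, traj.cc).statistic
        assert rho > 0.9

    def test_leave_one_out_reference_for_window_days(self):
        # the in-window day correlates with a reference excluding itself
        rng = np.random.default_rng(1)
        hs = {d: hist(rng.integers(0, 30, 10), day=d) for d in range(7)}
        ref = reference_pattern([hs[d] for d in range(7)])
        traj = cc_trajectory(hs, ref, reference_days=tuple(range(7)))
        loo_ref = reference_pattern([hs[d] for d in range(1, 7)],
                                    expected_days=6)
        assert traj.cc[0] == pytest.approx(pearson_cc(hs[0], loo_ref))


NOISELESS = (0.2, 0.7, 80.0, 15.0)


class TestFitDevelopmentCurve:
    def test_noiseless_parameter_recovery(self):
        days = np.arange(1, 201, dtype=float)
        fit = fit_development_curve(days, logistic(days, *NOISELESS))
        for got, want in zip((fit.a, fit.b, fit.c, fit.d_scale), NOISELESS):
            assert got == pytest.approx(want, abs=1e-3)
        assert fit.has_developmental_increase

    def test_constant_trajectory_shows_no_increase(self):
        days = np.arange(20, dtype=float)
        fit = fit_development_curve(days, np.full(20, 0.9))
        assert not fit.has_developmental_increase

    def test_decreasing_logistic_fits_with_negative_b(self):
        days = np.arange(1, 101, dtype=float)
        y = logistic(days, 0.9, -0.6, 40.0, 8.0)
        fit = fit_development_curve(days, y)
        assert fit.b == pytest.approx(-0.6, abs=1e-3)
        assert not fit.has_developmental_increase
        assert fit.rss < 1e-10

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 8"):
            fit_development_curve(np.arange(5.0), np.arange(5.0))


def _fit(a, b, c, d, has=True):
    return DevelopmentFit(a=a, b=b, c=c, d_scale=d, rss=0.0,
                          has_developmental_increase=has, converged=True,
                          n_points=100, day_range=(0.0, 300.0))


class TestStabilizationDay:
    def test_matches_closed_form_logistic_derivative(self):
        a, b, c, d = NOISELESS
        q = 0.001 * d / b
        p = 0.5 * (1 + math.sqrt(1 - 4 * q))
        x_star = c + d * math.log(p / (1 - p))
        got = stabilization_day(_fit(*NOISELESS))
        assert abs(got - x_star) < 1.0

    def test_sub_epsilon_rise_stabilizes_immediately(self):
        got = stabilization_day(_fit(0.2, 0.0005, 80.0, 15.0))
        assert got == math.ceil(80.0)

    def test_monotone_in_slope_scale(self):
        days = [stabilization_day(_fit(0.2, 0.7, 80.0, d))
                for d in (5.0, 10.0, 20.0, 40.0)]
        assert days == sorted(days)
        assert len(set(days)) == 4

    def test_no_rise_is_missing(self):
        assert math.isnan(stabilization_day(_fit(0.9, -0.2, 40.0, 5.0)))


class TestDmax:
    def test_matches_analytic_max_slope(self):
        got = dmax(_fit(*NOISELESS), (1, 200))
        assert got == pytest.approx(0.7 / (4 * 15.0), abs=1e-4)

    def test_flat_fit_is_missing(self):
        assert math.isnan(dmax(_fit(0.9, 0.0, 80.0, 15.0, has=False)))

    def test_translation_invariance_of_c(self):
        base = dmax(_fit(0.2, 0.7, 80.0, 15.0), (0, 300))
        shifted = dmax(_fit(0.2, 0.7, 130.0, 15.0), (0, 300))
        assert shifted == pytest.approx(base, abs=1e-12)


def _traj(days, cc):
    return SimilarityTrajectory(feature="SR", days=np.array(days),
                                cc=np.array(cc), reference_days=())


class TestDeteriorationRecovery:
    CAL = make_calendar(t1=(0, 199, 3), tm=(200, 274), t2=(275, 309, 278))

    def test_difference_of_window_means(self):
        days = list(range(190, 197)) + [278, 279] + list(range(300, 307))
        cc = [0.9] * 7 + [0.7, 0.7] + [0.95] * 7
        traj = _traj(days, cc)
        assert deterioration(traj, self.CAL) == pytest.approx(0.2)
        assert recovery(traj, self.CAL) == pytest.approx(0.25)

    def test_identical_windows_give_zero(self):
        days = list(range(190, 197)) + [278, 279]
        traj = _traj(days, [0.8] * 9)
        assert deterioration(traj, self.CAL) == pytest.approx(0.0)

    def test_flat_t2_gives_zero_recovery(self):
        days = list(range(278, 288))
        traj = _traj(days, [0.8] * 10)
        assert recovery(traj, self.CAL) == pytest.approx(0.0)

    def test_missing_window_is_missing(self):
        traj = _traj(list(range(190, 197)), [0.9] * 7)
        assert math.isnan(deterioration(traj, self.CAL))


class TestCrossTreatment:
    def _dataset(self, t2_values):
        rows = []
        for d in range(10, 17):  # 7 stable T1 days
            for k, v in enumerate([8.0] * 3 + [12.0] * 2):
                rows.append(("T1_PLUS", d, f"t1_{d}", k, "a", 50.0,
                             1000.0 / v - 50.0))
        for d in range(40, 47):
            for k, v in enumerate(t2_values):
                rows.append(("T2_PLUS", d, f"t2_{d}", k, "a", 50.0,
                             1000.0 / v - 50.0))
        rec = make_records(rows)
        cal = make_calendar(t1=(0, 20, 10), tm=(21, 35), t2=(36, 50, 40))
        return OntogenyDataset(bird_id="b1", calendar=cal, records=rec)

    def test_identical_stable_distributions_correlate_perfectly(self):
        ds = self._dataset([8.0] * 3 + [12.0] * 2)
        res = cross_treatment_similarity(ds, "SR", 1.0)
        assert res.cc_t1xt2 == pytest.approx(1.0)
        assert res.cc_t1xt1 == pytest.approx(1.0)

    def test_displaced_t2_distribution_decorrelates(self):
        ds = self._dataset([10.0] * 3 + [6.0] * 2)
        res = cross_treatment_similarity(ds, "SR", 1.0)
        assert res.cc_t1xt2 < 0.5
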