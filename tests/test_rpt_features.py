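import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from anxrpt import rpt_features as rpt


def _ratings_frame(per_category, participant="p1"):
    """Build a long-format 48-row table from a {category: [ratings]} mapping."""
    rows = []
    for cat, vals in per_category.items():
        assert len(vals) == 8
        for j, v in enumerate(vals):
            rows.append((participant, f"c{cat}_pic{j+1}", cat, v))
    return pd.DataFrame(rows, columns=["participant_id", "picture_id",
                                       "category", "rating"])


class TestSignedSummaries:
    def test_mean_variance_entropy_of_mixed_set(self):
        s = rpt.signed_summary([1, 1, 2, 3, -1, 0], "+")
        assert s.k == pytest.approx(1.75)
        assert s.sigma == pytest.approx(0.6875)   # population variance
        assert s.h == pytest.approx(1.5)          # p = (1/2, 1/4, 1/4)
        assert s.n == 4

    def test_degenerate_set_has_zero_entropy_and_variance(self):
        s = rpt.signed_summary([2, 2, 2, 2], "+")
        assert s.h == 0.0 and s.sigma == 0.0

    def test_uniform_three_outcomes_hits_entropy_bound(self):
        s = rpt.signed_summary([1, 2, 3], "+")
        assert s.h == pytest.approx(math.log2(3))

    def test_zeros_belong_to_neither_sign(self):
        assert rpt.signed_summary([0, 0, 0], "+") is None
        assert rpt.signed_summary([0, 0, 0], "-") is None
        s = rpt.signed_summary([0, -2, -3], "-")
        assert s.n == 2 and s.k == -2.5

    def test_sample_variance_flag(self):
        s = rpt.signed_summary([1, 3], "+", sample_variance=True)
        assert s.sigma == pytest.approx(2.0)

    @given(st.lists(st.integers(-3, 3), min_size=1, max_size=48))
    @settings(max_examples=100, deadline=None)
    def test_bounds_hold_for_any_rating_set(self, vals):
        for sign in ("+", "-"):
            s = rpt.signed_summary(vals, sign)
            if s is None:
                continue
            assert 0.0 <= s.h <= math.log2(3) + 1e-12
            assert 0.0 <= s.sigma <= 1.0  # same-sign values in {1,2,3}
            if sign == "+":
                assert 0 < s.k <= 3
            else:
                assert -3 <= s.k < 0


class TestValueFunction:
    H_GRID = np.array([0.5, 0.8, 1.1, 1.4, 1.7, 2.0])

    def test_exact_log_limb_recovery(self):
        k = 2.0 * np.log(self.H_GRID) + 1.0
        fit = rpt.fit_value_function(list(zip(self.H_GRID, k)), "+")
        assert fit.family == "log"
        assert fit.coefficients["a"] == pytest.approx(2.0, abs=1e-9)
        assert fit.coefficients["b"] == pytest.approx(1.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_exact_negative_log_limb_recovery(self):
        k = -3.0 * np.log(self.H_GRID) - 0.5
        fit = rpt.fit_value_function(list(zip(self.H_GRID, k)), "-")
        assert fit.coefficients["a"] == pytest.approx(-3.0, abs=1e-9)
        assert fit.coefficients["b"] == pytest.approx(-0.5, abs=1e-9)

    def test_exact_power_limb_selected_when_it_fits(self):
        k = 1.5 * self.H_GRID ** 0.8
        fit = rpt.fit_value_function(list(zip(self.H_GRID, k)), "+")
        assert fit.family == "power"
        assert fit.coefficients["a"] == pytest.approx(0.8, abs=1e-6)
        assert fit.coefficients["b"] == pytest.approx(1.5, abs=1e-6)

    def test_log_family_preferred_on_noisy_log_data(self):
        """Model selection favours the generating family on noisy data."""
        rng = np.random.default_rng(42)
        wins = 0
        for _ in range(100):
            k = 2.0 * np.log(self.H_GRID) + 1.0 + rng.normal(0, 0.05, 6)
            fit = rpt.fit_value_function(list(zip(self.H_GRID, k)), "+")
            wins += fit.family == "log"
        assert wins >= 90

    def test_zero_entropy_points_excluded(self):
        pts = [(0.0, 1.0)] + list(zip(self.H_GRID[:4],
                                      2.0 * np.log(self.H_GRID[:4]) + 1.0))
        fit = rpt.fit_value_function(pts, "+")
        assert fit.coefficients["a"] == pytest.approx(2.0, abs=1e-9)
        assert any("zero-entropy" in n for n in fit.notes)

    def test_too_few_points_returns_none(self):
        assert rpt.fit_value_function([(1.0, 2.0), (1.5, 2.5)], "+") is None

    def test_wrong_slope_sign_is_flagged(self):
        k = -1.0 * np.log(self.H_GRID) + 2.0  # falling positive limb
        fit = rpt.fit_value_function(list(zip(self.H_GRID, k)), "+")
        assert not fit.ok


class TestValueFeatures:
    @staticmethod
    def _log_fit(a, b):
        return rpt.CurveFit("log", {"a": a, "b": b}, 1.0, 1.0, np.inf, 6)

    @pytest.mark.parametrize("a_pos, a_neg, expected", [(2, -2, 1.0), (1, -3, 3.0)])
    def test_loss_aversion_is_limb_steepness_ratio(self, a_pos, a_neg, expected):
        feats = rpt.extract_value_features(
            self._log_fit(a_pos, 0.0), self._log_fit(a_neg, 0.0), 1.0, 1.0)
        assert feats["LA"] == pytest.approx(expected)

    def test_curvature_and_ante_of_log_limb(self):
        # K = 2 ln H + 1: |K''| = 2 / H^2 -> 0.5 at mean H = 2; Ante = K(1) = 1
        feats = rpt.extract_value_features(
            self._log_fit(2.0, 1.0), self._log_fit(-2.0, -1.0), 2.0, 1.0)
        assert feats["RA"] == pytest.approx(0.5)
        assert feats["Ante"] == pytest.approx(1.0)
        assert feats["Insurance"] == pytest.approx(1.0)
        assert feats["LR"] == pytest.approx(2.0)

    def test_nonpositive_positive_slope_leaves_la_undefined(self):
        feats = rpt.extract_value_features(
            self._log_fit(-1.0, 1.0), self._log_fit(-2.0, 0.0), 1.0, 1.0)
        assert math.isnan(feats["LA"])


class TestLimitFunction:
    K_GRID = np.array([-1.8, -1.2, -0.6, 0.6, 1.2, 1.8])

    def test_exact_quadratic_recovery(self):
        sigma = -self.K_GRID ** 2 + 4.0
        fit = rpt.fit_limit_function(list(zip(self.K_GRID, sigma)))
        assert fit.coefficients["alpha"] == pytest.approx(-1.0, abs=1e-9)
        assert fit.coefficients["beta"] == pytest.approx(0.0, abs=1e-9)
        assert fit.coefficients["gamma"] == pytest.approx(4.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_collinear_points_flagged_non_concave(self):
        fit = rpt.fit_limit_function(list(zip(self.K_GRID, np.ones(6))))
        assert not fit.ok

    def test_noisy_quadratic_alpha_within_tolerance(self):
        rng = np.random.default_rng(3)
        errs = []
        for _ in range(100):
            sigma = -self.K_GRID ** 2 + 4.0 + rng.normal(0, 0.05, 6)
            fit = rpt.fit_limit_function(list(zip(self.K_GRID, sigma)))
            errs.append(abs(fit.coefficients["alpha"] + 1.0))
        assert max(errs) < 0.1

    def test_symmetric_vertex_features(self):
        # sigma = -K^2 + 4: roots +-2, peak 4 at the open endpoint K -> 0
        sigma = -self.K_GRID ** 2 + 4.0
        feats = rpt.extract_limit_features(
            rpt.fit_limit_function(list(zip(self.K_GRID, sigma))))
        assert feats["RewardTP"] == pytest.approx(2.0, abs=1e-9)
        assert feats["AversionTP"] == pytest.approx(2.0, abs=1e-9)
        assert feats["TotalRR"] == pytest.approx(16.0 / 3.0, abs=1e-9)
        assert feats["TotalAR"] == pytest.approx(16.0 / 3.0, abs=1e-9)
        assert feats["PeakPR"] == pytest.approx(4.0, abs=1e-9)
        assert feats["PeakNR"] == pytest.approx(4.0, abs=1e-9)

    def test_offset_vertex_features(self):
        # sigma = -(K-1)^2 + 4: vertex in the approach domain, PeakNR at 0-
        sigma = -(self.K_GRID - 1.0) ** 2 + 4.0
        feats = rpt.extract_limit_features(
            rpt.fit_limit_function(list(zip(self.K_GRID, sigma))))
        assert feats["PeakPR"] == pytest.approx(4.0, abs=1e-9)
        assert feats["PeakNR"] == pytest.approx(3.0, abs=1e-9)
        assert feats["RewardTP"] == pytest.approx(3.0, abs=1e-9)
        assert feats["AversionTP"] == pytest.approx(1.0, abs=1e-9)

    def test_roots_not_straddling_zero_undefined(self):
        # concave but both roots positive: sigma = -(K-3)(K-5)
        k = np.array([2.5, 3.0, 3.5, 4.0, 4.5, 5.0])
        sigma = -(k - 3.0) * (k - 5.0)
        feats = rpt.extract_limit_features(rpt.fit_limit_function(list(zip(k, sigma))))
        assert all(math.isnan(v) for v in feats.values())

    def test_integrals_match_quadrature_on_random_concave_quadratics(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            alpha = -rng.uniform(0.2, 2.0)
            beta = rng.uniform(-0.5, 0.5)
            gamma = rng.uniform(1.0, 5.0)
            k = np.linspace(-2.0, 2.0, 8)
            sigma = alpha * k ** 2 + beta * k + gamma
            feats = rpt.extract_limit_features(
                rpt.fit_limit_function(list(zip(k, sigma))))
            f = lambda x: alpha * x ** 2 + beta * x + gamma
            r_pos, r_neg = feats["RewardTP"], -feats["AversionTP"]
            assert feats["TotalRR"] == pytest.approx(quad(f, 0, r_pos)[0], abs=1e-9)
            assert feats["TotalAR"] == pytest.approx(abs(quad(f, r_neg, 0)[0]), abs=1e-9)


class TestTradeoffFunction:
    def test_axis_points(self):
        fit = rpt.fit_tradeoff_function([(1.0, 0.0), (0.0, 1.0)])
        feats = rpt.extract_tradeoff_features(fit)
        assert feats["RATradeoff"] == pytest.approx(math.pi / 4)
        assert feats["TradeoffRange"] == pytest.approx(math.pi / 2)
        assert feats["RAConsistency"] == pytest.approx(1.0)
        assert feats["ConsistencyRange"] == pytest.approx(0.0)

    def test_diagonal_point(self):
        fit = rpt.fit_tradeoff_function([(1.0, 1.0), (2.0, 2.0)])
        feats = rpt.extract_tradeoff_features(fit)
        assert feats["RATradeoff"] == pytest.approx(math.pi / 4)
        assert feats["TradeoffRange"] == pytest.approx(0.0)
        assert feats["RAConsistency"] == pytest.approx((math.sqrt(2) + math.sqrt(8)) / 2)
        assert feats["ConsistencyRange"] == pytest.approx(math.sqrt(8) - math.sqrt(2))

    def test_identical_points_have_zero_spread(self):
        fit = rpt.fit_tradeoff_function([(1.2, 0.7)] * 6)
        feats = rpt.extract_tradeoff_features(fit)
        assert feats["TradeoffRange"] == 0.0
        assert feats["ConsistencyRange"] == 0.0

    def test_single_point_undefined(self):
        assert rpt.fit_tradeoff_function([(1.0, 1.0)]) is None
        assert rpt.fit_tradeoff_function([]) is None


class TestProfiles:
    def test_picture_order_invariance(self, small_cohort):
        """Shuffling pictures within categories leaves all 15 features unchanged."""
        ratings = small_cohort.ratings
        pid = ratings["participant_id"].iloc[0]
        mine = ratings[ratings["participant_id"] == pid]
        base = rpt.compute_profile(pid, mine).features
        rng = np.random.default_rng(0)
        shuffled = mine.sample(frac=1.0, random_state=1)
        perm = rpt.compute_profile(pid, shuffled).features
        for name in rpt.JUDGMENT_VARIABLES:
            if math.isnan(base[name]):
                assert math.isnan(perm[name])
            else:
                assert perm[name] == pytest.approx(base[name], rel=1e-12)

    def test_profiles_mostly_complete_on_synthetic_cohort(self, small_profiles):
        assert small_profiles["complete"].mean() > 0.8

    def test_wrong_length_table_raises(self):
        with pytest.raises(ValueError):
            rpt.summarize_ratings(_ratings_frame({1: [1] * 8}))


class TestRatingExclusions:
    def _uniform_table(self, value, pid):
        return _ratings_frame({c: [value] * 8 for c in range(1, 7)}, pid)

    def test_minimal_variance_rules(self, small_profiles, small_cohort):
        flat = self._uniform_table(3, "flat")
        near_flat = _ratings_frame({c: [1, 2, 1, 2, 1, 2, 1, 2] for c in range(1, 7)},
                                   "nearflat")
        ratings = pd.concat([small_cohort.ratings, flat, near_flat])
        profiles = pd.concat([
            small_profiles,
            pd.DataFrame({"complete": [False, False]}, index=["flat", "nearflat"]),
        ])
        report = rpt.apply_rating_exclusions(ratings, profiles)
        assert "minimal_rating_variance" in report.triggered["flat"]
        assert "minimal_rating_variance" in report.triggered["nearflat"]

    def test_full_span_complete_profile_retained(self, small_cohort, small_profiles):
        report = rpt.apply_rating_exclusions(small_cohort.ratings, small_profiles)
        retained = set(report.retained_ids)
        assert retained  # most of the cohort survives
        for pid in retained:
            assert bool(small_profiles.loc[pid, "complete"])

    def test_extreme_outlier_flagged(self, small_cohort, small_profiles):
        profiles = small_profiles.copy()
        victim = profiles.index[profiles["complete"]][0]
        profiles.loc[victim, "LA"] = 1e6
        report = rpt.apply_rating_exclusions(small_cohort.ratings, profiles)
        assert "extreme_outlier" in report.triggered[victim]
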