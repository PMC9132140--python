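import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special

from intelligrowth import (
    QuantileCurve,
    beta_quantile,
    beta_shape_from_location_scale,
    difference_slope,
    per_length_curves,
    percentile_curves,
    steepest_growth,
    threshold_age,
)


def bisect_beta_quantile(p, mu, sigma, tol=1e-12):
    """Independent inversion of the regularized incomplete beta CDF."""
    a, b = beta_shape_from_location_scale(mu, sigma)
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if special.betainc(a, b, mid) < p:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestShapes:
    def test_uniform_distribution(self):
        a, b = beta_shape_from_location_scale(0.5, np.sqrt(1.0 / 3.0))
        assert (a, b) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_worked_arithmetic(self):
        a, b = beta_shape_from_location_scale(0.57, 0.30)
        assert a == pytest.approx(0.57 * 0.91 / 0.09)
        assert b == pytest.approx(0.43 * 0.91 / 0.09)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(mu=st.floats(0.01, 0.99), sigma=st.floats(0.01, 0.99))
    def test_mean_identity(self, mu, sigma):
        a, b = beta_shape_from_location_scale(mu, sigma)
        assert a > 0 and b > 0
        assert a / (a + b) == pytest.approx(mu, rel=1e-9)

    @pytest.mark.parametrize("mu,sigma", [(0.0, 0.3), (1.0, 0.3), (0.5, 0.0), (0.5, 1.0)])
    def test_invalid_inputs_rejected(self, mu, sigma):
        with pytest.raises(ValueError):
            beta_shape_from_location_scale(mu, sigma)


class TestBetaQuantile:
    def test_symmetric_median(self):
        for sigma in (0.1, 0.3, 0.6):
            assert beta_quantile(0.5, 0.5, sigma) == pytest.approx(0.5, abs=1e-12)

    def test_matches_bisection_oracle_spot(self):
        q = beta_quantile(0.05, 0.57, 0.30)
        assert q == pytest.approx(bisect_beta_quantile(0.05, 0.57, 0.30), abs=1e-8)
        assert q == pytest.approx(0.32, abs=0.01)

    def test_upper_tail_stress(self):
        p = 0.999999
        assert beta_quantile(p, 0.57, 0.30) == pytest.approx(
            bisect_beta_quantile(p, 0.57, 0.30), abs=1e-4)

    def test_monotone_in_p(self):
        ps = np.linspace(0.01, 0.99, 50)
        qs = beta_quantile(ps, 0.6, 0.25)
        assert (np.diff(qs) > 0).all()

    def test_invalid_percentile(self):
        with pytest.raises(ValueError):
            beta_quantile(1.0, 0.5, 0.3)


class TestPercentileCurves:
    def test_pointwise_ordering(self, noceiling_fit):
        grid = np.arange(30.0, 120.0)
        c05, c50, c95 = percentile_curves(noceiling_fit, [0.05, 0.5, 0.95], grid)
        assert (c05.values <= c50.values).all()
        assert (c50.values <= c95.values).all()

    def test_concentration_limit(self, noceiling_fit):
        """With sigma forced to 0.01 every percentile hugs the mean curve."""
        import copy

        fit = copy.deepcopy(noceiling_fit)
        fit.coef_sigma_ = np.array([special.logit(0.01)] + [0.0] * (len(fit.coef_sigma_) - 1))
        grid = np.arange(30.0, 120.0)
        mu, _ = fit.predict_mu_sigma(grid)
        for curve in percentile_curves(fit, [0.05, 0.5, 0.95], grid):
            assert np.abs(curve.values - mu).max() < 0.03

    def test_median_curve_recovery(self, noceiling_fit, noceiling_config):
        from intelligrowth import true_quantile_curve

        grid = np.arange(30.0, 120.0)
        truth = true_quantile_curve(noceiling_config, 0.5, grid)
        (curve,) = percentile_curves(noceiling_fit, [0.5], grid)
        assert np.abs(100 * (curve.values - truth)).mean() < 2.5


def logistic_curve(percentile, k=0.1, t0=60.0, grid=None):
    grid = np.arange(30.0, 120.0, 0.1) if grid is None else grid
    return QuantileCurve(percentile, grid, special.expit(k * (grid - t0)))


class TestThresholdAge:
    def test_analytic_logistic_crossing(self):
        grid = np.arange(30.0, 121.0, 1.0)
        est = threshold_age(logistic_curve(0.5, k=0.1, t0=60.0, grid=grid), 0.5)
        assert est.censor == "exact"
        assert est.age == pytest.approx(60.0, abs=1.0)

    def test_censored_below_grid_minimum(self):
        grid = np.arange(30.0, 121.0, 1.0)
        curve = QuantileCurve(0.5, grid, np.linspace(0.55, 0.99, len(grid)))
        est = threshold_age(curve, 0.5)
        assert est.censor == "at_or_below_min" and est.age == 30.0

    def test_censored_beyond_grid_maximum(self):
        grid = np.arange(30.0, 121.0, 1.0)
        curve = QuantileCurve(0.5, grid, np.linspace(0.2, 0.85, len(grid)))
        est = threshold_age(curve, 0.90)
        assert est.censor == "at_or_beyond_max" and est.age == 120.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(shift=st.floats(-10.0, 10.0))
    def test_shift_equivariance(self, shift):
        grid = np.arange(30.0, 121.0, 1.0)
        base = threshold_age(logistic_curve(0.5, grid=grid), 0.5)
        shifted_curve = QuantileCurve(0.5, grid + shift, special.expit(0.1 * (grid - 60.0)))
        shifted = threshold_age(shifted_curve, 0.5)
        assert shifted.age - base.age == pytest.approx(shift, abs=1e-9)

    def test_nonfinite_curve_rejected(self):
        grid = np.arange(30.0, 121.0, 1.0)
        vals = np.linspace(0.2, 0.9, len(grid))
        vals[5] = np.nan
        with pytest.raises(ValueError):
            threshold_age(QuantileCurve(0.5, grid, vals), 0.5)


class TestSteepestGrowth:
    @pytest.mark.parametrize("k", [0.05, 0.1, 0.2])
    def test_logistic_peak_and_rate(self, k):
        peak = steepest_growth(logistic_curve(0.5, k=k, t0=60.0))
        assert peak.age == pytest.approx(60.0, abs=0.1)
        assert peak.rate == pytest.approx(100 * k / 4, rel=0.01)
        assert not peak.truncated

    def test_linear_curve_earliest_age_tie_break(self):
        # exactly representable values so the derivative ties exactly
        n = 360
        grid = 30.0 + 0.25 * np.arange(n)
        peak = steepest_growth(QuantileCurve(0.5, grid, np.arange(n) / 1024.0))
        assert peak.age == 30.0
        assert peak.truncated

    def test_left_truncation_when_peak_precedes_grid(self):
        peak = steepest_growth(logistic_curve(0.5, k=0.1, t0=25.0))
        assert peak.age == 30.0
        assert peak.truncated

    def test_coarse_grid_rejected(self):
        grid = np.arange(30.0, 121.0, 1.0)
        with pytest.raises(ValueError, match="coarse"):
            steepest_growth(QuantileCurve(0.5, grid, special.expit(0.1 * (grid - 60.0))))


class TestDifferenceSlope:
    @staticmethod
    def _cohort(n, slope_pp, seed=0):
        rng = np.random.default_rng(seed)
        ages = rng.uniform(48, 119, n)
        single = rng.uniform(0.5, 0.8, n)
        gap = (5.0 + slope_pp * (ages - 48.0)) / 100.0 + rng.normal(0, 0.01, n)
        return pd.DataFrame({"age_months": ages, "single_word": single, "multiword": single + gap})

    def test_constant_gap_gives_null_slope(self):
        slope, (lo, hi), _ = difference_slope(self._cohort(400, 0.0), min_age=48.0)
        assert lo < 0.0 < hi
        assert abs(slope) < 0.05

    def test_planted_slope_recovered(self):
        slope, _, _ = difference_slope(self._cohort(400, 0.1), min_age=48.0)
        assert 0.07 < slope < 0.13

    def test_age_filter_row_count(self):
        young = self._cohort(100, 0.0, seed=1)
        young["age_months"] = np.linspace(30, 47.9, 100)
        both = pd.concat([young, self._cohort(300, 0.0, seed=2)], ignore_index=True)
        _, _, n = difference_slope(both, min_age=48.0)
        assert n == 300

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            difference_slope(self._cohort(5, 0.0), min_age=48.0)


class TestPerLengthCurves:
    def test_bookkeeping_and_observed_only(self, default_cohort):
        children, _ = default_cohort
        fits = per_length_curves(children)
        assert set(fits) == set(range(1, 8))
        assert fits[1].n_obs_ == len(children)
        assert fits[7].n_obs_ == (children.longest_length == 7).sum()

    def test_exchangeable_lengths_agree(self):
        """When every length shares the generative law (no offsets, no
        ceiling), the per-length mean curves agree pairwise within 3 points."""
        from intelligrowth import CeilingLaw, SimulationConfig, TrueGrowthLaw, simulate_cohort

        cfg = SimulationConfig(
            n_children=2000, seed=6, age_sampling="uniform",
            true_growth=TrueGrowthLaw(length_offsets={}), ceiling=CeilingLaw.none())
        fits = per_length_curves(simulate_cohort(cfg), lengths=(1, 4, 7))
        grid = np.arange(30.0, 120.0)
        curves = {L: f.predict(grid) for L, f in fits.items()}
        for La, Lb in [(1, 4), (4, 7), (1, 7)]:
            assert np.abs(100 * (curves[La] - curves[Lb])).mean() < 3.0
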