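"""Parametric-bootstrap confidence intervals for growth-curve summaries.

Uncertainty is propagated by sampling coefficient vectors from the
multivariate normal distribution centred at the fitted coefficients with the
robust (sandwich) variance-covariance matrix, recomputing the quantile
growth curves for every draw, and taking empirical .025/.975 quantiles of
the per-draw statistics.  Threshold-age draws pinned at the age-grid bounds
contribute the bound value; a confidence limit sitting at a bound is flagged
and rendered "<= min" / ">= max".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .growth import BetaGrowthCurve
from .quantiles import beta_shape_from_location_scale

__all__ = [
    "ParameterDraws",
    "IntervalEstimate",
    "draw_parameters",
    "ci_quantiles",
    "curve_bands",
    "threshold_interval",
    "peak_intervals",
]

_MIN_DRAWS_95 = 40


@dataclass(frozen=True)
class ParameterDraws:
    """Sampled coefficient vectors, one row per draw."""

    draws: np.ndarray
    seed: int

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]


@dataclass(frozen=True)
class IntervalEstimate:
    point: float
    lo: float
    hi: float
    level: float = 0.95
    censor_lo: bool = False
    censor_hi: bool = False

    def render(self, fmt: str = "{:.0f}", lo_label: str | None = None,
               hi_label: str | None = None) -> str:
        lo = lo_label if (self.censor_lo and lo_label) else fmt.format(self.lo)
        hi = hi_label if (self.censor_hi and hi_label) else fmt.format(self.hi)
        return f"{fmt.format(self.point)} [{lo}, {hi}]"


def draw_parameters(fit: BetaGrowthCurve, n_draws: int, seed: int) -> ParameterDraws:
    """Draw coefficient vectors from MVN(theta_hat, vcov_robust).

    The covariance square root comes from an eigendecomposition; tiny
    negative eigenvalues (rounding noise, above -1e-10) are clipped to zero,
    anything more negative aborts as a genuinely indefinite matrix.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    V = np.asarray(fit.vcov_robust_, dtype=float)
    V = 0.5 * (V + V.T)
    w, Q = np.linalg.eigh(V)
    if np.any(w < -1e-10):
        raise ValueError(f"robust vcov is not PSD (min eigenvalue {w.min():.3e})")
    root = Q * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_draws, len(w)))
    return ParameterDraws(draws=fit.theta_ + Z @ root.T, seed=int(seed))


def ci_quantiles(values, level: float = 0.95):
    """Empirical (1-level)/2 and 1-(1-level)/2 quantiles of the draws.

    Uses the linear-interpolation order-statistic rule (numpy's default
    "linear" method); recorded in output metadata for reproducibility.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < _MIN_DRAWS_95:
        raise ValueError(f"need at least {_MIN_DRAWS_95} finite draws, got {v.size}")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(v, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def _mu_sigma_draws(fit: BetaGrowthCurve, draws: ParameterDraws, ages: np.ndarray):
    """mu and sigma per (age, draw): arrays of shape (n_ages, n_draws)."""
    from scipy.special import expit

    Xm, Xs = fit._design(np.asarray(ages, dtype=float))
    pm = len(fit.coef_mu_)
    Bm = draws.draws[:, :pm]
    Bs = draws.draws[:, pm:]
    return expit(Xm @ Bm.T), expit(Xs @ Bs.T)


def _quantile_draw_matrix(fit, draws, ages, percentile):
    mu, sig = _mu_sigma_draws(fit, draws, ages)
    bad = (mu <= 0) | (mu >= 1) | (sig <= 0) | (sig >= 1)
    if bad.any():  # expit output can only hit the boundary by overflow
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        sig = np.clip(sig, 1e-12, 1 - 1e-12)
    a, b = beta_shape_from_location_scale(mu, sig)
    return stats.beta.ppf(percentile, a, b)  # (n_ages, n_draws)


def _check_failures(Qd, what: str):
    frac_bad = 1.0 - np.isfinite(Qd).all(axis=0).mean()
    if frac_bad > 0.01:
        raise RuntimeError(f"{what} failed on {frac_bad:.1%} of parameter draws")


def curve_bands(fit: BetaGrowthCurve, draws: ParameterDraws, percentile: float,
                ages, level: float = 0.95) -> list[IntervalEstimate]:
    """Pointwise CIs for one percentile curve at each requested age."""
    ages = np.asarray(ages, dtype=float)
    point = fit.predict_quantile(ages, percentile)
    Qd = _quantile_draw_matrix(fit, draws, ages, percentile)
    _check_failures(Qd, "quantile-curve propagation")
    out = []
    for j in range(len(ages)):
        lo, hi = ci_quantiles(Qd[j], level)
        out.append(IntervalEstimate(float(point[j]), lo, hi, level))
    return out


def _threshold_ages_vectorized(t: np.ndarray, V: np.ndarray, threshold: float):
    """Per-draw first-crossing ages with bound substitution at the grid ends.

    V is (n_ages, n_draws); returns (ages, at_lo, at_hi) per draw.
    """
    n_ages, n_draws = V.shape
    above = V >= threshold
    first = np.argmax(above, axis=0)
    any_above = above.any(axis=0)
    at_lo = above[0]
    at_hi = ~any_above
    i = np.clip(first, 1, n_ages - 1)
    cols = np.arange(n_draws)
    v1, v0 = V[i, cols], V[i - 1, cols]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (threshold - v0) / (v1 - v0)
    ages = t[i - 1] + frac * (t[i] - t[i - 1])
    ages = np.where(at_lo, t[0], ages)
    ages = np.where(at_hi, t[-1], ages)
    return ages, at_lo, at_hi


def threshold_interval(fit: BetaGrowthCurve, draws: ParameterDraws, percentile: float,
                       threshold: float, ages, level: float = 0.95) -> IntervalEstimate:
    """CI for the age at which a percentile curve reaches a threshold.

    Draws censored at the grid bounds enter with the bound value, so a CI
    endpoint equal to a bound is flagged censored (rendered "<= min" /
    ">= max", the growth-chart convention for ages outside the study range).
    """
    from .quantiles import QuantileCurve, threshold_age

    t = np.asarray(ages, dtype=float)
    est = threshold_age(QuantileCurve(percentile, t, fit.predict_quantile(t, percentile)), threshold)
    V = _quantile_draw_matrix(fit, draws, t, percentile)
    _check_failures(V, "threshold propagation")
    age_draws, _, _ = _threshold_ages_vectorized(t, V, threshold)
    lo, hi = ci_quantiles(age_draws, level)
    return IntervalEstimate(
        point=est.age, lo=lo, hi=hi, level=level,
        censor_lo=bool(lo <= t[0]), censor_hi=bool(hi >= t[-1]),
    )


def peak_intervals(fit: BetaGrowthCurve, draws: ParameterDraws, percentile: float,
                   ages, level: float = 0.95) -> tuple[IntervalEstimate, IntervalEstimate]:
    """CIs for the age of steepest growth and the maximum growth rate.

    Returns ``(age_interval, rate_interval)``; rate in percentage points per
    month.  Peak-age draws at the grid start reflect left truncation at the
    youngest study age and flag the lower limit accordingly.
    """
    from .quantiles import QuantileCurve, steepest_growth

    t = np.asarray(ages, dtype=float)
    peak = steepest_growth(QuantileCurve(percentile, t, fit.predict_quantile(t, percentile)))
    V = _quantile_draw_matrix(fit, draws, t, percentile)
    _check_failures(V, "growth-peak propagation")
    D = np.gradient(V, t, axis=0)
    idx = np.argmax(D, axis=0)
    age_draws = t[idx]
    rate_draws = 100.0 * D[idx, np.arange(V.shape[1])]
    alo, ahi = ci_quantiles(age_draws, level)
    rlo, rhi = ci_quantiles(rate_draws, level)
    age_iv = IntervalEstimate(peak.age, alo, ahi, level,
                              censor_lo=bool(alo <= t[0]), censor_hi=bool(ahi >= t[-1]))
    rate_iv = IntervalEstimate(peak.rate, rlo, rhi, level)
    return age_iv, rate_iv
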