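"""Percentile growth curves and their summaries.

Given a fitted beta location-scale model, each percentile ``p`` traces a
curve ``q_p(age) = F_beta^{-1}(p; mu(age), sigma(age))`` — the chart line a
clinician would read as "the p-th percentile child".  From those curves we
extract the two clinically meaningful summaries:

* **threshold ages** — the youngest age at which the curve reaches a stated
  intelligibility level (50%, 75%, 90%), censored at the study age bounds
  when the level is already met at the youngest age or never met;
* **age and rate of steepest growth** — the maximizer of the curve's
  derivative and the derivative there, in percentage points per month.

Also here: the per-utterance-length descriptive fits (observed data only)
and the multiword-minus-single-word difference-slope regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .growth import BetaGrowthCurve, fit_beta_growth, squeeze_unit_interval

__all__ = [
    "QuantileCurve",
    "ThresholdEstimate",
    "GrowthPeak",
    "beta_shape_from_location_scale",
    "beta_quantile",
    "percentile_curves",
    "threshold_age",
    "steepest_growth",
    "difference_slope",
    "per_length_curves",
]


def beta_shape_from_location_scale(mu, sigma):
    """Map (mu, sigma) with Var = sigma^2 mu (1-mu) to beta shape parameters.

    shape1 = mu (1 - sigma^2) / sigma^2, shape2 = (1 - mu) (1 - sigma^2) / sigma^2.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any((mu <= 0) | (mu >= 1)):
        raise ValueError("mu must lie strictly in (0, 1)")
    if np.any((sigma <= 0) | (sigma >= 1)):
        raise ValueError("sigma must lie strictly in (0, 1)")
    phi = (1.0 - sigma**2) / sigma**2
    return mu * phi, (1.0 - mu) * phi


def beta_quantile(p, mu, sigma):
    """Quantile of the beta distribution in the location-scale parameterization."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("percentile p must lie strictly in (0, 1)")
    a, b = beta_shape_from_location_scale(mu, sigma)
    return stats.beta.ppf(p, a, b)


@dataclass(frozen=True)
class QuantileCurve:
    """One percentile's intelligibility as a function of age on a grid."""

    percentile: float
    ages: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(ages) <= 0):
            raise ValueError("age grid must be strictly increasing")
        if ages.shape != values.shape:
            raise ValueError("ages and values must align")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class ThresholdEstimate:
    threshold: float
    percentile: float
    age: float
    censor: str  # "exact" | "at_or_below_min" | "at_or_beyond_max"


@dataclass(frozen=True)
class GrowthPeak:
    percentile: float
    age: float
    rate: float  # percentage points per month
    truncated: bool


def percentile_curves(fit: BetaGrowthCurve, percentiles, ages) -> list[QuantileCurve]:
    ages = np.asarray(ages, dtype=float)
    mu, sig = fit.predict_mu_sigma(ages)
    return [QuantileCurve(float(p), ages, beta_quantile(float(p), mu, sig)) for p in percentiles]


def threshold_age(curve: QuantileCurve, threshold: float) -> ThresholdEstimate:
    """Age at which the percentile curve first reaches ``threshold``.

    Censoring: a curve already at or above the threshold at the grid start
    is reported at the grid minimum ("<= min"); a curve that never reaches
    it is reported at the grid maximum (">= max").
    """
    v = curve.values
    if not np.isfinite(v).all():
        raise ValueError("curve contains non-finite values")
    t = curve.ages
    if v[0] >= threshold:
        return ThresholdEstimate(threshold, curve.percentile, float(t[0]), "at_or_below_min")
    above = v >= threshold
    if not above.any():
        return ThresholdEstimate(threshold, curve.percentile, float(t[-1]), "at_or_beyond_max")
    i = int(np.argmax(above))  # first index at/above; i >= 1 here
    frac = (threshold - v[i - 1]) / (v[i] - v[i - 1])
    age = t[i - 1] + frac * (t[i] - t[i - 1])
    return ThresholdEstimate(threshold, curve.percentile, float(age), "exact")


def steepest_growth(curve: QuantileCurve, max_step: float = 0.5) -> GrowthPeak:
    """Age maximizing the curve's derivative, and the rate there (pp/month).

    Central differences on the grid; ties broken toward the earliest age;
    ``truncated`` flags a maximizer pinned to either grid end (the true peak
    may lie outside the observed age range).
    """
    t, v = curve.ages, curve.values
    step = np.max(np.diff(t))
    if step > max_step:
        raise ValueError(f"grid step {step:.3g} months too coarse for derivative analysis (max {max_step})")
    deriv = np.gradient(v, t)
    i = int(np.argmax(deriv))  # argmax returns the first maximizer
    return GrowthPeak(
        percentile=curve.percentile,
        age=float(t[i]),
        rate=float(100.0 * deriv[i]),
        truncated=bool(i == 0 or i == len(t) - 1),
    )


def difference_slope(scores, min_age: float = 48.0, level: float = 0.95):
    """OLS slope of (multiword - single-word) intelligibility on age.

    ``scores`` is a DataFrame with columns ``age_months``, ``single_word``
    and ``multiword`` (proportions).  Only children at or above ``min_age``
    enter.  Returns ``(slope, (lo, hi), n)`` with the slope in percentage
    points per month and a t-based confidence interval.
    """
    import statsmodels.api as sm

    sub = scores.loc[scores["age_months"] >= min_age]
    n = len(sub)
    if n < 10:
        raise ValueError(f"need at least 10 children at or above {min_age} months, got {n}")
    diff_pp = 100.0 * (sub["multiword"].to_numpy(float) - sub["single_word"].to_numpy(float))
    X = sm.add_constant(sub["age_months"].to_numpy(float))
    res = sm.OLS(diff_pp, X).fit()
    lo, hi = res.conf_int(alpha=1.0 - level)[1]
    return float(res.params[1]), (float(lo), float(hi)), n


def per_length_curves(cohort, lengths=range(1, 8), **fit_kwargs) -> dict[int, BetaGrowthCurve]:
    """One independent beta growth fit per utterance length, observed data only.

    No imputation and no weighting: the length-L fit uses exactly the
    children whose ceiling reached L (all children for single words).
    """
    fits: dict[int, BetaGrowthCurve] = {}
    for L in lengths:
        col = f"score_len{L}"
        obs = cohort.loc[cohort[col].notna()]
        y = squeeze_unit_interval(obs[col].to_numpy(float), len(obs))
        fits[L] = fit_beta_growth(obs["age_months"].to_numpy(float), y, **fit_kwargs)
    return fits
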