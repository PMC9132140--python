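"""End-to-end analysis: cohort table in, growth-chart tables out.

Single-word and multiword intelligibility are analyzed separately with the
same modelling approach: impute-and-weight the multiword composite, squeeze
scores off the [0, 1] boundary, fit the beta location-scale growth model,
extract percentile curves, threshold ages and steepest-growth summaries,
and attach parametric-bootstrap confidence intervals.  All randomness flows
from the single configured seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .bootstrap import IntervalEstimate, draw_parameters, peak_intervals, threshold_interval
from .growth import BetaGrowthCurve, fit_beta_growth, squeeze_unit_interval
from .imputation import LengthImputer, LengthWeightModel, composite_for_cohort
from .quantiles import difference_slope, percentile_curves
from .scoring import icc_oneway_average

__all__ = ["AnalysisConfig", "ResultBundle", "run_full_analysis", "observed_summary",
           "OBSERVED_SUMMARY_BANDS"]

#: age bands (months, inclusive) used for the observed-summary table
OBSERVED_SUMMARY_BANDS = ((30, 35), (36, 47), (48, 59), (60, 71), (72, 83), (84, 95), (96, 119))

OUTCOMES = ("single_word", "multiword")


@dataclass(frozen=True)
class AnalysisConfig:
    percentiles: tuple = (0.05, 0.10, 0.50, 0.90, 0.95)
    thresholds: tuple = (0.50, 0.75, 0.90)
    location_df: int = 3
    scale_df: int = 2
    n_draws: int = 10_000
    seed: int = 0
    age_min: float = 30.0
    age_max: float = 120.0
    threshold_step: float = 1.0
    peak_step: float = 0.1
    weight_method: str = "logistic"
    difference_min_age: float = 48.0
    use_imputation: bool = True

    def __post_init__(self):
        if any(not 0.0 < t < 1.0 for t in self.thresholds):
            raise ValueError("thresholds must lie strictly in (0, 1)")
        if list(self.percentiles) != sorted(self.percentiles):
            raise ValueError("percentile set must be sorted ascending")
        if self.n_draws < 1:
            raise ValueError("n_draws must be positive")

    def threshold_grid(self) -> np.ndarray:
        return np.arange(self.age_min, self.age_max + 1e-9, self.threshold_step)

    def peak_grid(self) -> np.ndarray:
        return np.arange(self.age_min, self.age_max - 1.0 + 1e-9, self.peak_step)


@dataclass
class ResultBundle:
    config: AnalysisConfig
    scores: pd.DataFrame
    fits: dict[str, BetaGrowthCurve]
    quantile_table: pd.DataFrame
    threshold_table: pd.DataFrame
    peak_table: pd.DataFrame
    observed_table: pd.DataFrame
    difference_slope: dict
    imputation_audit: pd.DataFrame
    icc: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


def _fit_hash(fit: BetaGrowthCurve) -> str:
    payload = json.dumps(fit.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _render_age(iv: IntervalEstimate, lo_bound: float, hi_bound: float) -> str:
    point = f"≥ {hi_bound:.0f}" if iv.point >= hi_bound else f"{iv.point:.0f}"
    lo = f"≤ {lo_bound:.0f}" if iv.censor_lo else f"{iv.lo:.0f}"
    hi = f"≥ {hi_bound:.0f}" if iv.censor_hi else f"{iv.hi:.0f}"
    return f"{point} [{lo}, {hi}]"


def observed_summary(scores: pd.DataFrame, age_bands=OBSERVED_SUMMARY_BANDS) -> pd.DataFrame:
    """Observed (model-free) means and SDs by age band, in percent.

    One row per band: n, single-word and multiword mean/SD.  A band with a
    single child reports its SD as missing; an empty band is kept with a
    flag rather than silently dropped.
    """
    rows = []
    for lo, hi in age_bands:
        sub = scores.loc[(scores["age_months"] >= lo) & (scores["age_months"] <= hi)]
        row = {"band": f"{lo}–{hi}", "n": len(sub), "empty": len(sub) == 0}
        for col in OUTCOMES:
            vals = 100.0 * sub[col].dropna().to_numpy(float)
            row[f"{col}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{col}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _child_scores(cohort: pd.DataFrame, config: AnalysisConfig):
    """Impute, weight, and assemble one single-word and one multiword score
    per child.  Children whose ceiling is below two words have no multiword
    composite and carry NaN there."""
    imputer = LengthImputer().fit(cohort)
    if config.use_imputation:
        complete = imputer.transform(cohort)
    else:  # only sensible on cohorts with no missing lengths
        complete = cohort.copy()
        imputer.imputation_audit_ = pd.DataFrame(columns=["child_id", "length", "value", "note"])
    weight_model = LengthWeightModel(method=config.weight_method).fit(
        cohort["age_months"].to_numpy(float), cohort["longest_length"].to_numpy(int)
    )
    scores = cohort[["child_id", "age_months", "sex", "longest_length"]].copy()
    scores["single_word"] = cohort["score_len1"].to_numpy(float)
    anchored = complete["longest_length"] >= 2
    comp = pd.Series(np.nan, index=complete.index)
    comp.loc[anchored] = composite_for_cohort(complete.loc[anchored], weight_model)
    scores["multiword"] = comp
    return scores, imputer, weight_model


def run_full_analysis(cohort: pd.DataFrame, config: AnalysisConfig | None = None,
                      listener_scores: pd.DataFrame | None = None) -> ResultBundle:
    """Run the whole analysis on a child-level cohort table.

    ``cohort`` needs columns ``child_id, age_months, longest_length,
    score_len1..score_len7``.  ``listener_scores`` (optional, long format
    with ``child_id, listener, length, score``) adds listener-agreement
    ICCs to the bundle.
    """
    config = config or AnalysisConfig()
    t0 = time.perf_counter()
    timings: dict[str, float] = {}

    scores, imputer, weight_model = _child_scores(cohort, config)
    timings["scoring"] = time.perf_counter() - t0

    fits: dict[str, BetaGrowthCurve] = {}
    for outcome in OUTCOMES:
        sub = scores.loc[scores[outcome].notna()]
        y = squeeze_unit_interval(sub[outcome].to_numpy(float), len(sub))
        fits[outcome] = fit_beta_growth(
            sub["age_months"].to_numpy(float), y,
            location_df=config.location_df, scale_df=config.scale_df,
        )
    timings["fits"] = time.perf_counter() - t0 - sum(timings.values())

    tgrid = config.threshold_grid()
    pgrid = config.peak_grid()
    draws = {o: draw_parameters(fits[o], config.n_draws, seed=config.seed + i)
             for i, o in enumerate(OUTCOMES)}

    # Model-estimated percentile table at 6-month band midpoints
    band_starts = np.arange(config.age_min, config.age_max - 1.0, 6.0)
    mids = band_starts + 2.5
    qrows = {"band": [f"{int(s)}–{int(s) + 5}" for s in band_starts]}
    for outcome in OUTCOMES:
        for curve in percentile_curves(fits[outcome], config.percentiles, mids):
            qrows[f"{outcome}_p{int(round(curve.percentile * 100))}"] = np.round(100.0 * curve.values, 1)
    quantile_table = pd.DataFrame(qrows)

    th_rows, pk_rows = [], []
    for outcome in OUTCOMES:
        for p in config.percentiles:
            for thr in config.thresholds:
                iv = threshold_interval(fits[outcome], draws[outcome], p, thr, tgrid)
                th_rows.append({
                    "outcome": outcome, "percentile": p, "threshold": thr,
                    "age": iv.point, "lo": iv.lo, "hi": iv.hi,
                    "censor_lo": iv.censor_lo, "censor_hi": iv.censor_hi,
                    "rendered": _render_age(iv, tgrid[0], tgrid[-1]),
                })
            age_iv, rate_iv = peak_intervals(fits[outcome], draws[outcome], p, pgrid)
            pk_rows.append({
                "outcome": outcome, "percentile": p,
                "peak_age": age_iv.point, "peak_age_lo": age_iv.lo, "peak_age_hi": age_iv.hi,
                "left_truncated": age_iv.censor_lo,
                "rate": rate_iv.point, "rate_lo": rate_iv.lo, "rate_hi": rate_iv.hi,
                "rendered_age": _render_age(age_iv, pgrid[0], pgrid[-1]),
            })
    timings["uncertainty"] = time.perf_counter() - t0 - sum(timings.values())

    slope, (slo, shi), n_slope = difference_slope(scores.dropna(subset=["multiword"]),
                                                 min_age=config.difference_min_age)

    icc = {}
    if listener_scores is not None:
        for outcome, sel in (("single_word", listener_scores["length"] == 1),
                             ("multiword", listener_scores["length"] > 1)):
            sub = listener_scores.loc[sel]
            agg = sub.groupby(["child_id", "listener"], as_index=False).apply(
                lambda g: pd.Series({"score": np.average(g["score"], weights=g["words"])}),
                include_groups=False,
            )
            mat = agg.pivot(index="child_id", columns="listener", values="score").dropna()
            res = icc_oneway_average(mat.to_numpy())
            icc[outcome] = {"icc": res.icc_estimate, "ci": [res.ci_low, res.ci_high],
                            "n_subjects": res.n_subjects}

    metadata = {
        "package_version": __version__,
        "seed": config.seed,
        "n_draws": config.n_draws,
        "quantile_rule": "linear-interpolation order statistics (numpy 'linear')",
        "fit_hashes": {o: _fit_hash(f) for o, f in fits.items()},
        "config_hash": hashlib.sha256(repr(config).encode()).hexdigest()[:16],
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    return ResultBundle(
        config=config,
        scores=scores,
        fits=fits,
        quantile_table=quantile_table,
        threshold_table=pd.DataFrame(th_rows),
        peak_table=pd.DataFrame(pk_rows),
        observed_table=observed_summary(scores),
        difference_slope={"slope_pp_per_month": slope, "ci": [slo, shi], "n": n_slope,
                          "min_age": config.difference_min_age},
        imputation_audit=imputer.imputation_audit_,
        icc=icc,
        metadata=metadata,
    )
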