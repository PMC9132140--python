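"""Imputation-weighting of multiword intelligibility.

The sentence-repetition protocol stops at the first length a child cannot
complete, so young children are missing scores at the longer lengths — a
testing artifact, not a property of their speech.  Averaging only observed
lengths would bias multiword intelligibility.  The remedy implemented here:

1. For each target length L in 3..7, train a regression predicting
   length-L intelligibility from the child's longest utterance length and
   the intelligibilities at every shorter length, using only children who
   actually produced length L.
2. Fill each child's missing lengths in ascending order, carrying each
   imputed value forward as a predictor for the next length.
3. Average lengths 2..7 with age-based weights proportional to the
   probability of producing each length at the child's age (fitted
   per-length logistic regressions of "reached length L" on age, nested by
   isotonization), normalized to sum to one.

Regressions run on the logit scale (boundary scores nudged inward) so
back-transformed imputations stay inside [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "LengthWeights",
    "LengthImputer",
    "LengthWeightModel",
    "fit_imputation_models",
    "impute_profile",
    "fit_length_probability",
    "length_weights",
    "multiword_composite",
    "composite_for_cohort",
]

MULTIWORD_LENGTHS = tuple(range(2, 8))
_SCORE_COLS = {L: f"score_len{L}" for L in range(1, 8)}


def _safe_logit(y: np.ndarray, eps: float) -> np.ndarray:
    return logit(np.clip(y, eps, 1.0 - eps))


class LengthImputer(BaseEstimator, TransformerMixin):
    """Sequential carried-forward regression imputation of length scores.

    Parameters
    ----------
    boundary_eps : float
        Scores are clipped to ``[eps, 1 - eps]`` before the logit transform;
        interior scores are untouched.

    Attributes
    ----------
    models_ : dict
        Per target length L in 3..7 either ``{"coef", "n", "resid_sd"}``
        (coefficients ordered intercept, logit scores 1..L-1,
        longest_length) or None when too few training children exist.
    """

    def __init__(self, boundary_eps: float = 0.005):
        self.boundary_eps = boundary_eps

    def fit(self, cohort: pd.DataFrame, y=None):
        self.models_: dict[int, dict | None] = {}
        for L in range(3, 8):
            obs = cohort.loc[cohort[_SCORE_COLS[L]].notna()]
            n_pred = L  # scores 1..L-1 plus longest_length
            if len(obs) < n_pred + 2:
                warnings.warn(f"too few children with observed length-{L} scores; model unavailable")
                self.models_[L] = None
                continue
            X = np.column_stack(
                [np.ones(len(obs))]
                + [_safe_logit(obs[_SCORE_COLS[l]].to_numpy(float), self.boundary_eps) for l in range(1, L)]
                + [obs["longest_length"].to_numpy(float)]
            )
            z = _safe_logit(obs[_SCORE_COLS[L]].to_numpy(float), self.boundary_eps)
            coef, _, _, _ = np.linalg.lstsq(X, z, rcond=None)
            if not np.isfinite(coef).all():
                raise RuntimeError(f"non-finite imputation coefficients for length {L}")
            resid = z - X @ coef
            dof = max(len(obs) - X.shape[1], 1)
            self.models_[L] = {
                "coef": coef,
                "n": int(len(obs)),
                "resid_sd": float(np.sqrt(resid @ resid / dof)),
            }
        return self

    def transform(self, cohort: pd.DataFrame) -> pd.DataFrame:
        """Return a copy with missing lengths filled; observed cells untouched.

        Children whose ceiling is below two words have no multiword data to
        anchor the chain; they are left unchanged and flagged in
        ``imputation_audit_`` with length 0.
        """
        if not hasattr(self, "models_"):
            raise RuntimeError("LengthImputer is not fitted")
        out = cohort.copy()
        audit = []
        no_anchor = out["longest_length"] < 2
        for cid in out.loc[no_anchor, "child_id"]:
            audit.append({"child_id": cid, "length": 0, "value": np.nan, "note": "no multiword data"})
        for L in range(3, 8):
            col = _SCORE_COLS[L]
            need = out[col].isna() & ~no_anchor
            if not need.any():
                continue
            model = self.models_[L]
            if model is None:
                raise RuntimeError(f"imputation model for length {L} unavailable but needed")
            rows = out.loc[need]
            X = np.column_stack(
                [np.ones(len(rows))]
                + [_safe_logit(rows[_SCORE_COLS[l]].to_numpy(float), self.boundary_eps) for l in range(1, L)]
                + [rows["longest_length"].to_numpy(float)]
            )
            pred = np.clip(expit(X @ model["coef"]), 0.0, 1.0)
            out.loc[need, col] = pred
            audit.extend(
                {"child_id": cid, "length": L, "value": v, "note": "imputed"}
                for cid, v in zip(rows["child_id"], pred)
            )
        self.imputation_audit_ = pd.DataFrame(audit, columns=["child_id", "length", "value", "note"])
        return out


def fit_imputation_models(cohort: pd.DataFrame, boundary_eps: float = 0.005) -> LengthImputer:
    return LengthImputer(boundary_eps=boundary_eps).fit(cohort)


def impute_profile(profile, models: LengthImputer) -> pd.Series:
    """Impute a single child's length profile (Series with score_len columns)."""
    row = pd.DataFrame([profile])
    if "child_id" not in row.columns:
        row["child_id"] = 0
    return models.transform(row).iloc[0]


class LengthWeightModel(BaseEstimator):
    """Age-dependent probability of reaching each utterance length.

    ``method='logistic'`` (default) fits one logistic regression of the
    indicator {longest_length >= L} on age per length; ``'empirical'`` uses
    raw 6-month band proportions; ``'ordinal'`` fits a single
    proportional-odds model.  Fitted probabilities are nested
    (P(reach L) >= P(reach L+1)) by isotonization across lengths.
    """

    def __init__(self, method: str = "logistic", coef_bound: float = 2.0):
        self.method = method
        self.coef_bound = coef_bound

    def fit(self, ages, longest):
        ages = np.asarray(ages, dtype=float)
        longest = np.asarray(longest, dtype=int)
        if np.unique(ages).size < 3:
            raise ValueError("need at least 3 distinct ages to model length probabilities")
        if self.method == "logistic":
            self._fit_logistic(ages, longest)
        elif self.method == "empirical":
            self._fit_empirical(ages, longest)
        elif self.method == "ordinal":
            self._fit_ordinal(ages, longest)
        else:
            raise ValueError(f"unknown method {self.method!r}")
        return self

    def _fit_logistic(self, ages, longest):
        import statsmodels.api as sm

        self.coef_: dict[int, tuple[float, float]] = {}
        X = sm.add_constant(ages)
        for L in MULTIWORD_LENGTHS:
            y = (longest >= L).astype(float)
            if y.min() == y.max():
                # degenerate indicator: constant probability with a light
                # Laplace nudge off the boundary
                p = (y.sum() + 0.5) / (len(y) + 1.0)
                self.coef_[L] = (float(logit(p)), 0.0)
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
            b0, b1 = float(res.params[0]), float(res.params[1])
            if not np.isfinite([b0, b1]).all() or abs(b1) > self.coef_bound:
                warnings.warn(f"separation in length-{L} probability model; bounding the age coefficient")
                from sklearn.linear_model import LogisticRegression

                lr = LogisticRegression(C=10.0).fit(ages[:, None], y)
                b0, b1 = float(lr.intercept_[0]), float(lr.coef_[0, 0])
                b1 = float(np.clip(b1, -self.coef_bound, self.coef_bound))
            self.coef_[L] = (b0, b1)

    def _fit_empirical(self, ages, longest):
        edges = np.arange(np.floor(ages.min() / 6) * 6, ages.max() + 6.0, 6.0)
        self.band_edges_ = edges
        idx = np.clip(np.digitize(ages, edges) - 1, 0, len(edges) - 2)
        self.band_probs_ = np.full((len(edges) - 1, len(MULTIWORD_LENGTHS)), np.nan)
        for b in range(len(edges) - 1):
            in_b = idx == b
            if in_b.any():
                for j, L in enumerate(MULTIWORD_LENGTHS):
                    self.band_probs_[b, j] = np.mean(longest[in_b] >= L)
        # forward/backward fill empty bands
        df = pd.DataFrame(self.band_probs_).ffill().bfill()
        self.band_probs_ = df.to_numpy()

    def _fit_ordinal(self, ages, longest):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        cats = np.sort(np.unique(longest))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            endog = pd.Series(pd.Categorical(longest, categories=cats, ordered=True))
            res = OrderedModel(endog, ages[:, None], distr="logit").fit(method="bfgs", disp=False)
        self._ordinal_res_ = res
        self._ordinal_cats_ = cats

    def predict_proba(self, ages) -> pd.DataFrame:
        """P(reach length L | age) for L = 2..7, nested across lengths."""
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        if self.method == "logistic":
            P = np.column_stack([expit(b0 + b1 * ages) for (b0, b1) in self.coef_.values()])
        elif self.method == "empirical":
            idx = np.clip(np.digitize(ages, self.band_edges_) - 1, 0, self.band_probs_.shape[0] - 1)
            P = self.band_probs_[idx]
        else:
            probs = self._ordinal_res_.predict(ages[:, None])  # (n, n_cats)
            P = np.column_stack([
                np.asarray(probs)[:, self._ordinal_cats_ >= L].sum(axis=1)
                for L in MULTIWORD_LENGTHS
            ])
        P = np.minimum.accumulate(P, axis=1)  # enforce nesting
        return pd.DataFrame(P, columns=list(MULTIWORD_LENGTHS), index=ages)


@dataclass(frozen=True)
class LengthWeights:
    """Normalized simplex weights over utterance lengths 2..7 at one age."""

    age_months: float
    weights: dict

    def __post_init__(self):
        w = np.asarray(list(self.weights.values()), dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.asarray([self.weights[L] for L in MULTIWORD_LENGTHS], dtype=float)


def fit_length_probability(cohort: pd.DataFrame, method: str = "logistic") -> LengthWeightModel:
    return LengthWeightModel(method=method).fit(
        cohort["age_months"].to_numpy(float), cohort["longest_length"].to_numpy(int)
    )


def length_weights(age: float, prob_model: LengthWeightModel) -> LengthWeights:
    raw = prob_model.predict_proba([age]).iloc[0].to_numpy()
    total = raw.sum()
    if total <= 0:
        raise ValueError(f"all length probabilities are zero at age {age}")
    w = raw / total
    w = w / w.sum()  # renormalize exactly
    return LengthWeights(age_months=float(age), weights=dict(zip(MULTIWORD_LENGTHS, w)))


def multiword_composite(profile, weights: LengthWeights) -> float:
    """Weighted average of a complete profile's length-2..7 scores."""
    scores = np.asarray([profile[_SCORE_COLS[L]] for L in MULTIWORD_LENGTHS], dtype=float)
    if np.isnan(scores).any():
        raise ValueError("profile must be complete over lengths 2..7 (impute first)")
    return float(scores @ weights.as_array())


def composite_for_cohort(complete_cohort: pd.DataFrame, prob_model: LengthWeightModel) -> pd.Series:
    """Vectorized multiword composite for every child in a complete cohort."""
    ages = complete_cohort["age_months"].to_numpy(float)
    W = prob_model.predict_proba(ages).to_numpy()
    W = W / W.sum(axis=1, keepdims=True)
    S = complete_cohort[[_SCORE_COLS[L] for L in MULTIWORD_LENGTHS]].to_numpy(float)
    vals = np.einsum("ij,ij->i", W, S)
    return pd.Series(vals, index=complete_cohort.index, name="multiword")
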