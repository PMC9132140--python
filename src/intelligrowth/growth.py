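"""Beta location-scale regression of intelligibility on age.

The outcome (proportion of words correctly transcribed) is modelled as beta
distributed with both parameters varying smoothly with age:

    y | age  ~  Beta(a(age), b(age)),
    a = mu (1 - sigma^2) / sigma^2,     b = (1 - mu) (1 - sigma^2) / sigma^2,

so that E[y] = mu and Var[y] = sigma^2 mu (1 - mu), with mu, sigma in (0, 1).
Both mu and sigma are linked through the logit to natural cubic spline
functions of age (3 df for the location, 2 df for the scale, by default).
This is the location/scale parameterization in which a "precision" of 0.3
with a mean of 0.57 pins down the whole distribution of scores at an age,
and in particular every percentile of it.

Fitting is by maximum likelihood with an analytic gradient; both the
model-based (inverse observed information) and the robust sandwich
variance-covariance matrices of the stacked coefficients are computed, the
latter being what the parametric bootstrap samples from.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

from .splines import SplineSpec, natural_cubic_basis

__all__ = [
    "BetaGrowthCurve",
    "fit_beta_growth",
    "predict_mu_sigma",
    "quantile_residuals",
    "squeeze_unit_interval",
]

_EXPIT = special.expit
_LOGIT = special.logit


def squeeze_unit_interval(y, n: int) -> np.ndarray:
    """Compress scores from [0, 1] into the open interval (0, 1).

    Uses ``y' = (y (n - 1) + 0.5) / n`` with ``n`` the sample size, the
    standard remedy for boundary observations under a beta likelihood.
    Order-preserving, and 0.5 is a fixed point for every ``n``.
    """
    y = np.asarray(y, dtype=float)
    if n < 1:
        raise ValueError(f"n must be a positive count, got {n}")
    if np.any((y < 0) | (y > 1) | ~np.isfinite(y)):
        raise ValueError("scores must lie in [0, 1]")
    return (y * (n - 1) + 0.5) / n


def _loglik_terms(theta, Xm, Xs, y, logy, log1my):
    pm = Xm.shape[1]
    eta_m = Xm @ theta[:pm]
    eta_s = Xs @ theta[pm:]
    mu = _EXPIT(eta_m)
    sig = _EXPIT(eta_s)
    phi = (1.0 - sig**2) / sig**2          # a + b
    a = mu * phi
    b = (1.0 - mu) * phi
    ll = special.gammaln(phi) - special.gammaln(a) - special.gammaln(b) \
        + (a - 1.0) * logy + (b - 1.0) * log1my
    return ll, mu, sig, phi, a, b


def _score_matrix(theta, Xm, Xs, y, logy, log1my):
    """Per-observation gradient of the log-likelihood, (n, p)."""
    ll, mu, sig, phi, a, b = _loglik_terms(theta, Xm, Xs, y, logy, log1my)
    dg_phi = special.digamma(phi)
    la = dg_phi - special.digamma(a) + logy
    lb = dg_phi - special.digamma(b) + log1my
    dmu = phi * (la - lb) * mu * (1.0 - mu)                      # d ll / d eta_mu
    dsig = (-2.0 / sig**3) * (mu * la + (1.0 - mu) * lb) * sig * (1.0 - sig)
    return np.hstack([Xm * dmu[:, None], Xs * dsig[:, None]]), ll


def _make_objective(Xm, Xs, y):
    logy = np.log(y)
    log1my = np.log1p(-y)
    n = y.size

    def fun(theta):
        ll, *_ = _loglik_terms(theta, Xm, Xs, y, logy, log1my)
        return -ll.sum() / n

    def jac(theta):
        S, _ = _score_matrix(theta, Xm, Xs, y, logy, log1my)
        return -S.sum(axis=0) / n

    def scores(theta):
        S, ll = _score_matrix(theta, Xm, Xs, y, logy, log1my)
        return S, ll

    return fun, jac, scores


def _numerical_hessian(jac, theta, rel_step=1e-5):
    p = theta.size
    H = np.empty((p, p))
    for j in range(p):
        h = rel_step * max(1.0, abs(theta[j]))
        tp = theta.copy(); tp[j] += h
        tm = theta.copy(); tm[j] -= h
        H[:, j] = (jac(tp) - jac(tm)) / (2.0 * h)
    return 0.5 * (H + H.T)


class BetaGrowthCurve(BaseEstimator):
    """Maximum-likelihood beta location-scale growth curve.

    Parameters
    ----------
    location_df, scale_df : int
        Spline degrees of freedom for logit(mu) and logit(sigma).
    location_spec, scale_spec : SplineSpec, optional
        Explicit knot layouts; by default knots are placed from the
        training ages (boundary at min/max, interior at quantiles).
    tol : float
        Convergence tolerance on the 2-norm of the mean log-likelihood
        gradient.
    max_iter : int
        Iteration cap for the quasi-Newton optimizer.

    Attributes
    ----------
    coef_mu_, coef_sigma_ : ndarray
        Fitted coefficients (intercept first) for the two linear predictors.
    theta_ : ndarray
        The stacked coefficient vector ``[coef_mu_, coef_sigma_]``.
    loglik_ : float
        Maximized total log-likelihood.
    vcov_model_, vcov_robust_ : ndarray
        Inverse observed information and sandwich covariance of ``theta_``.
    converged_ : bool
    n_obs_ : int
    """

    def __init__(self, location_df: int = 3, scale_df: int = 2,
                 location_spec: SplineSpec | None = None,
                 scale_spec: SplineSpec | None = None,
                 tol: float = 1e-6, max_iter: int = 500):
        self.location_df = location_df
        self.scale_df = scale_df
        self.location_spec = location_spec
        self.scale_spec = scale_spec
        self.tol = tol
        self.max_iter = max_iter

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _ages(X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError("X must be a single age column")
            x = x[:, 0]
        return x

    def _design(self, ages):
        Xm = np.column_stack([np.ones_like(ages), natural_cubic_basis(ages, self.location_spec_)])
        if self.scale_spec_ is None:  # constant dispersion (scale_df=0)
            Xs = np.ones((len(ages), 1))
        else:
            Xs = np.column_stack([np.ones_like(ages), natural_cubic_basis(ages, self.scale_spec_)])
        return Xm, Xs

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y):
        ages = self._ages(X)
        y = np.asarray(y, dtype=float)
        if ages.shape != y.shape:
            raise ValueError("X and y must have matching lengths")
        ok = np.isfinite(ages) & np.isfinite(y)
        if not ok.all():
            raise ValueError("non-finite ages or scores; clean or squeeze the data first")
        if np.any((y <= 0.0) | (y >= 1.0)):
            raise ValueError(
                "scores must lie strictly inside (0, 1); apply squeeze_unit_interval "
                "to boundary observations before fitting"
            )
        if y.size < 30 or np.unique(ages).size < 5:
            raise ValueError("need at least 30 observations spanning at least 5 distinct ages")
        if np.ptp(y) == 0.0:
            raise ValueError("degenerate data: all scores identical")

        self.location_spec_ = self.location_spec or SplineSpec.from_data(ages, self.location_df)
        if self.scale_spec is not None:
            self.scale_spec_ = self.scale_spec
        elif self.scale_df >= 1:
            self.scale_spec_ = SplineSpec.from_data(ages, self.scale_df)
        else:
            self.scale_spec_ = None
        Xm, Xs = self._design(ages)
        fun, jac, scores = _make_objective(Xm, Xs, y)

        ybar = y.mean()
        sig0 = np.sqrt(y.var() / (ybar * (1.0 - ybar)))
        sig0 = float(np.clip(sig0, 0.05, 0.95))
        theta0 = np.zeros(Xm.shape[1] + Xs.shape[1])
        theta0[0] = _LOGIT(ybar)
        theta0[Xm.shape[1]] = _LOGIT(sig0)

        theta, gnorm = self._optimize(fun, jac, theta0)
        if gnorm >= self.tol:
            # single deterministic restart from a perturbed start
            theta1, gnorm1 = self._optimize(fun, jac, theta0 + 0.1)
            if gnorm1 < gnorm:
                theta, gnorm = theta1, gnorm1
        self.converged_ = bool(gnorm < self.tol)
        if not self.converged_:
            warnings.warn(f"beta growth fit did not reach tolerance: |grad| = {gnorm:.2e}")

        n = y.size
        S, ll = scores(theta)
        Hmean = _numerical_hessian(jac, theta)        # hessian of mean NLL
        A = Hmean                                      # average negative Hessian of ll
        Ainv = np.linalg.inv(A)
        B = (S.T @ S) / n
        vcov_model = Ainv / n
        vcov_robust = Ainv @ B @ Ainv / n
        self.theta_ = theta
        self.coef_mu_ = theta[:Xm.shape[1]].copy()
        self.coef_sigma_ = theta[Xm.shape[1]:].copy()
        self.loglik_ = float(ll.sum())
        self.vcov_model_ = 0.5 * (vcov_model + vcov_model.T)
        self.vcov_robust_ = 0.5 * (vcov_robust + vcov_robust.T)
        self.grad_norm_ = float(gnorm)
        self.n_obs_ = int(n)
        return self

    def _optimize(self, fun, jac, theta0):
        res = optimize.minimize(fun, theta0, jac=jac, method="BFGS",
                                options={"gtol": 1e-10, "maxiter": self.max_iter})
        theta = res.x
        # Newton polish: BFGS can stall just above a tight gradient tolerance
        for _ in range(25):
            g = jac(theta)
            if np.linalg.norm(g) < self.tol:
                break
            H = _numerical_hessian(jac, theta)
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                break
            f0 = fun(theta)
            lam = 1.0
            while lam > 1e-6 and not fun(theta - lam * step) <= f0:
                lam /= 2.0
            if lam <= 1e-6:
                break
            theta = theta - lam * step
        return theta, float(np.linalg.norm(jac(theta)))

    def predict(self, X) -> np.ndarray:
        """Predicted mean intelligibility mu(age)."""
        return self.predict_mu_sigma(X)[0]

    def predict_sigma(self, X) -> np.ndarray:
        return self.predict_mu_sigma(X)[1]

    def predict_mu_sigma(self, X):
        self._check_fitted()
        ages = self._ages(X)
        if np.any((ages < 0) | (ages > 200)):
            raise ValueError("ages outside [0, 200] months look like a unit error (years vs months?)")
        Xm, Xs = self._design(ages)
        return _EXPIT(Xm @ self.coef_mu_), _EXPIT(Xs @ self.coef_sigma_)

    def predict_quantile(self, X, p: float) -> np.ndarray:
        """The p-th conditional quantile of intelligibility at each age."""
        from .quantiles import beta_quantile  # local import to avoid a cycle
        mu, sig = self.predict_mu_sigma(X)
        return beta_quantile(p, mu, sig)

    def _check_fitted(self):
        if not hasattr(self, "theta_"):
            raise RuntimeError("this BetaGrowthCurve instance is not fitted yet")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "location_spec": self.location_spec_.to_dict(),
            "scale_spec": None if self.scale_spec_ is None else self.scale_spec_.to_dict(),
            "coef_mu": self.coef_mu_.tolist(),
            "coef_sigma": self.coef_sigma_.tolist(),
            "loglik": self.loglik_,
            "vcov_model": self.vcov_model_.tolist(),
            "vcov_robust": self.vcov_robust_.tolist(),
            "converged": self.converged_,
            "grad_norm": self.grad_norm_,
            "n_obs": self.n_obs_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BetaGrowthCurve":
        loc = SplineSpec.from_dict(d["location_spec"])
        sca = None if d["scale_spec"] is None else SplineSpec.from_dict(d["scale_spec"])
        est = cls(location_df=loc.df, scale_df=0 if sca is None else sca.df,
                  location_spec=loc, scale_spec=sca)
        est.location_spec_, est.scale_spec_ = loc, sca
        est.coef_mu_ = np.asarray(d["coef_mu"], dtype=float)
        est.coef_sigma_ = np.asarray(d["coef_sigma"], dtype=float)
        est.theta_ = np.concatenate([est.coef_mu_, est.coef_sigma_])
        est.loglik_ = float(d["loglik"])
        est.vcov_model_ = np.asarray(d["vcov_model"], dtype=float)
        est.vcov_robust_ = np.asarray(d["vcov_robust"], dtype=float)
        est.converged_ = bool(d["converged"])
        est.grad_norm_ = float(d["grad_norm"])
        est.n_obs_ = int(d["n_obs"])
        return est


def fit_beta_growth(ages, scores, location_spec: SplineSpec | None = None,
                    scale_spec: SplineSpec | None = None, *,
                    location_df: int = 3, scale_df: int = 2, **kwargs) -> BetaGrowthCurve:
    """Fit the beta location-scale growth model to (age, score) pairs."""
    est = BetaGrowthCurve(location_df=location_df, scale_df=scale_df,
                          location_spec=location_spec, scale_spec=scale_spec, **kwargs)
    return est.fit(np.asarray(ages, dtype=float), np.asarray(scores, dtype=float))


def predict_mu_sigma(fit: BetaGrowthCurve, ages):
    return fit.predict_mu_sigma(ages)


def quantile_residuals(fit: BetaGrowthCurve, ages, scores) -> np.ndarray:
    """Randomized-free quantile residuals: Phi^{-1}(F_beta(y_i | mu_i, sigma_i)).

    Standard normal under a correctly specified model; the usual beta
    regression diagnostic.
    """
    from .quantiles import beta_shape_from_location_scale
    mu, sig = fit.predict_mu_sigma(ages)
    a, b = beta_shape_from_location_scale(mu, sig)
    u = stats.beta.cdf(np.asarray(scores, dtype=float), a, b)
    return stats.norm.ppf(u)
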