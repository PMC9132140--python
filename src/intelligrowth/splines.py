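"""Natural cubic spline bases for age effects.

A natural cubic spline is cubic between its knots, has continuous second
derivatives everywhere, and is constrained to be *linear* beyond its boundary
knots.  That boundary behaviour is what makes it the standard choice for
growth-chart covariates: extrapolation beyond the observed age range stays
tame instead of exploding cubically.

The basis used here is the truncated-power natural basis: with knots
``xi_1 < ... < xi_K`` (boundary knots first and last), the ``df = K - 1``
columns are the identity function plus the ``K - 2`` curvature functions

    N_{k+1}(x) = d_k(x) - d_{K-1}(x),
    d_k(x) = [ (x - xi_k)_+^3 - (x - xi_K)_+^3 ] / (xi_K - xi_k).

The span of these functions (plus an intercept, supplied by the regression
design) is exactly the natural cubic spline space on those knots.  Ages are
rescaled to [0, 1] over the boundary interval before the cubics are formed so
the design stays well conditioned for month-scale inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SplineSpec", "natural_cubic_basis"]


@dataclass(frozen=True)
class SplineSpec:
    """Knot layout for a natural cubic spline basis of dimension ``df``.

    ``df`` counts basis columns excluding the intercept; a valid spec has
    ``df - 1`` interior knots strictly inside the boundary knots.
    """

    df: int
    boundary_knots: tuple[float, float]
    interior_knots: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        lo, hi = self.boundary_knots
        if not np.isfinite([lo, hi]).all() or not lo < hi:
            raise ValueError(f"boundary_knots must be finite and increasing, got {self.boundary_knots}")
        if self.df < 1:
            raise ValueError(f"df must be >= 1, got {self.df}")
        ik = np.asarray(self.interior_knots, dtype=float)
        if len(ik) != self.df - 1:
            raise ValueError(
                f"df={self.df} requires {self.df - 1} interior knots, got {len(ik)}"
            )
        if len(ik) and (np.any(np.diff(ik) <= 0) or ik[0] <= lo or ik[-1] >= hi):
            raise ValueError("interior knots must be strictly increasing and strictly inside the boundary knots")

    @property
    def all_knots(self) -> np.ndarray:
        lo, hi = self.boundary_knots
        return np.asarray([lo, *self.interior_knots, hi], dtype=float)

    @classmethod
    def from_data(cls, x, df: int) -> "SplineSpec":
        """Boundary knots at the data min/max, interior knots at equally
        spaced quantiles (the usual default for regression splines)."""
        x = np.asarray(x, dtype=float)
        x = x[np.isfinite(x)]
        if x.size < 2:
            raise ValueError("need at least two finite values to place knots")
        lo, hi = float(x.min()), float(x.max())
        if df == 1:
            return cls(df=1, boundary_knots=(lo, hi))
        probs = np.arange(1, df) / df
        interior = np.quantile(x, probs)
        interior = np.clip(interior, lo + 1e-8, hi - 1e-8)
        if np.any(np.diff(interior) <= 0):
            # fall back to equally spaced knots under heavy ties
            interior = lo + (hi - lo) * probs
        return cls(df=df, boundary_knots=(lo, hi), interior_knots=tuple(float(v) for v in interior))

    def to_dict(self) -> dict:
        return {
            "df": self.df,
            "boundary_knots": list(self.boundary_knots),
            "interior_knots": list(self.interior_knots),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSpec":
        return cls(
            df=int(d["df"]),
            boundary_knots=tuple(d["boundary_knots"]),
            interior_knots=tuple(d.get("interior_knots", ())),
        )


def natural_cubic_basis(x, spec: SplineSpec) -> np.ndarray:
    """Evaluate the natural cubic spline basis at ``x``.

    Returns an ``(n, spec.df)`` array.  No intercept column is included.
    The function is purely pointwise: evaluating on different grids gives
    identical values at shared points.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if not np.isfinite(x).all():
        raise ValueError("ages must be finite to evaluate the spline basis")
    lo, hi = spec.boundary_knots
    scale = hi - lo
    z = (x - lo) / scale
    cols = [z]
    if spec.df > 1:
        knots = (spec.all_knots - lo) / scale
        zK = knots[-1]

        def d(k: int) -> np.ndarray:
            return (np.clip(z - knots[k], 0.0, None) ** 3 - np.clip(z - zK, 0.0, None) ** 3) / (zK - knots[k])

        dlast = d(len(knots) - 2)
        for k in range(len(knots) - 2):
            cols.append(d(k) - dlast)
    return np.column_stack(cols)
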