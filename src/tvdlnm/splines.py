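"""Natural cubic spline and linear basis construction.

Natural cubic splines are the workhorse of distributed-lag temperature
modelling: piecewise cubics constrained to be linear beyond their boundary
knots, which stabilises the fitted exposure-response curve in the sparse
tails of the temperature distribution.

The construction here follows the standard recipe: build the cubic B-spline
design matrix on the knot sequence, then project onto the null space of the
two second-derivative constraints at the boundary knots.  Outside the
boundary knots the basis is continued linearly (value plus first derivative
at the boundary), so evaluation is exact everywhere.  Any basis of the
natural-spline space is acceptable downstream -- fitted risk surfaces are
parameterization-invariant -- so the particular orthonormal null-space basis
chosen here is a numerical convenience, not a modelling choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import null_space

__all__ = [
    "BasisSpec",
    "ns_basis",
    "place_exposure_knots",
    "place_lag_knots",
]


@dataclass(frozen=True)
class BasisSpec:
    """Specification of a one-dimensional basis.

    Parameters
    ----------
    kind : {"ns", "linear", "const"}
        Natural cubic spline, linear, or intercept-only basis.
    interior_knots : tuple of float
        Strictly increasing knots strictly inside the boundary knots
        (ignored for non-spline kinds).
    boundary_knots : tuple of float
        Pair ``(a, b)`` with ``a < b`` (ignored for ``const``).
    intercept : bool
        Whether the basis spans the constant function on its own.

    Notes
    -----
    Dimension is ``len(interior_knots) + 1 + intercept`` for natural cubic
    splines and ``1 + intercept`` for linear bases, mirroring the convention
    of the DLNM literature where the exposure basis carries no intercept and
    the lag basis does.
    """

    kind: str
    interior_knots: tuple = field(default=())
    boundary_knots: tuple = field(default=(0.0, 1.0))
    intercept: bool = False

    def __post_init__(self):
        object.__setattr__(self, "interior_knots",
                           tuple(float(k) for k in self.interior_knots))
        object.__setattr__(self, "boundary_knots",
                           tuple(float(k) for k in self.boundary_knots))
        if self.kind not in ("ns", "linear", "const"):
            raise ValueError(f"unknown basis kind {self.kind!r}")
        if self.kind == "const":
            return
        a, b = self.boundary_knots
        if not (np.isfinite(a) and np.isfinite(b)):
            raise ValueError("boundary knots must be finite")
        if not a < b:
            raise ValueError(f"degenerate boundary knots ({a}, {b})")
        ks = self.interior_knots
        if any(not np.isfinite(k) for k in ks):
            raise ValueError("non-finite interior knot")
        if any(k2 <= k1 for k1, k2 in zip(ks, ks[1:])):
            raise ValueError("interior knots must be strictly increasing")
        if ks and (ks[0] <= a or ks[-1] >= b):
            raise ValueError("interior knots must lie strictly inside the "
                             f"boundary knots ({a}, {b}); got {ks}")

    @property
    def dim(self) -> int:
        if self.kind == "const":
            return 1
        if self.kind == "linear":
            return 1 + int(self.intercept)
        return len(self.interior_knots) + 1 + int(self.intercept)


@lru_cache(maxsize=256)
def _ns_machinery(interior: tuple, boundary: tuple, intercept: bool):
    """Knot vector, null-space projection and boundary value/slope rows."""
    a, b = boundary
    knots = np.r_[[a] * 4, interior, [b] * 4]
    nb = len(interior) + 4
    bs = BSpline(knots, np.eye(nb), 3, extrapolate=True)
    d2 = bs.derivative(2)
    # natural constraint: zero curvature at both boundary knots
    constraint = np.vstack([d2(a), d2(b)])
    Z = null_space(constraint)                      # nb x (nb - 2)
    if not intercept:
        # the coefficient vector of ones represents the constant function
        # (partition of unity) and satisfies the constraints; remove it
        u = Z.T @ np.ones(nb)
        Z = Z @ null_space(u[None, :])              # nb x (nb - 3)
    val_a = bs(a) @ Z
    val_b = bs(b) @ Z
    d1 = bs.derivative(1)
    slope_a = d1(a) @ Z
    slope_b = d1(b) @ Z
    return knots, Z, val_a, slope_a, val_b, slope_b


def ns_basis(x, spec: BasisSpec) -> np.ndarray:
    """Evaluate the basis described by ``spec`` at the points ``x``.

    Missing (NaN) entries of ``x`` propagate to NaN rows.  For natural
    splines, points outside the boundary knots are evaluated on the linear
    extension of the boundary value and slope, so the natural constraint is
    honoured exactly during extrapolation.

    Returns
    -------
    ndarray of shape ``(len(x), spec.dim)``.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if spec.kind == "const":
        out = np.ones((len(x), 1))
        out[~np.isfinite(x)] = np.nan
        return out[0] if scalar else out
    if spec.kind == "linear":
        cols = [x] if not spec.intercept else [np.ones_like(x), x]
        out = np.column_stack(cols)
        out[~np.isfinite(x)] = np.nan
        return out[0] if scalar else out

    knots, Z, val_a, slope_a, val_b, slope_b = _ns_machinery(
        spec.interior_knots, spec.boundary_knots, spec.intercept)
    a, b = spec.boundary_knots
    out = np.full((len(x), Z.shape[1]), np.nan)
    ok = np.isfinite(x)
    xc = np.clip(x[ok], a, b)
    design = BSpline.design_matrix(xc, knots, 3).toarray()
    B = design @ Z
    below = x[ok] < a
    above = x[ok] > b
    if below.any():
        B[below] = val_a + np.outer(x[ok][below] - a, slope_a)
    if above.any():
        B[above] = val_b + np.outer(x[ok][above] - b, slope_b)
    out[ok] = B
    return out[0] if scalar else out


def place_exposure_knots(tmean, percentiles=(75.0,)) -> BasisSpec:
    """Exposure-dimension spec: knots at empirical temperature percentiles.

    Interior knots sit at the requested percentiles of the observed series
    (linear-interpolation percentile rule); boundary knots at the observed
    minimum and maximum.  No intercept: the exposure basis is centred by the
    model reference temperature instead.
    """
    t = np.asarray(tmean, dtype=float)
    t = t[np.isfinite(t)]
    if t.size == 0:
        raise ValueError("cannot place exposure knots: all temperatures missing")
    pct = tuple(float(p) for p in percentiles)
    if any(not 0.0 < p < 100.0 for p in pct):
        raise ValueError(f"percentiles must be in (0, 100); got {pct}")
    lo, hi = float(t.min()), float(t.max())
    if not lo < hi:
        raise ValueError("degenerate temperature series (constant); cannot "
                         "place boundary knots")
    interior = tuple(float(np.percentile(t, p)) for p in sorted(pct))
    return BasisSpec("ns", interior, (lo, hi), intercept=False)


def place_lag_knots(max_lag: int, n_knots: int) -> BasisSpec:
    """Lag-dimension spec: knots equally spaced on the log-lag scale.

    Knots are ``exp`` of ``n_knots`` points equally spaced strictly between
    ``log(1) = 0`` and ``log(max_lag)``; boundary knots at ``(0, max_lag)``;
    with intercept (the lag basis must represent lag-constant effects).
    Degenerate geometries (a knot coinciding with a boundary) fall back to a
    linear lag basis.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1 for a lag spline")
    if n_knots < 1:
        raise ValueError("n_knots must be >= 1")
    pts = np.linspace(0.0, np.log(max_lag), n_knots + 2)[1:-1]
    knots = np.exp(pts)
    eps = 1e-9
    if (knots <= eps) .any() or (knots >= max_lag - eps).any() or \
            len(np.unique(np.round(knots, 12))) < len(knots):
        return BasisSpec("linear", (), (0.0, float(max_lag)), intercept=True)
    return BasisSpec("ns", tuple(knots), (0.0, float(max_lag)), intercept=True)
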