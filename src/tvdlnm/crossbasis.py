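"""Bi-dimensional exposure-lag crossbasis construction.

The crossbasis is the tensor product of an exposure basis R (temperature
dimension) and a lag basis C (evaluated at integer lags 0..max_lag):

    CB[t, (i, j)] = sum_{l=0}^{L} R_i(x_{t-l}) * C_j(l)

Columns are exposure-major: column ``i * vl + j`` pairs exposure function i
with lag function j.  Rows whose trailing exposure window is incomplete
(the first ``max_lag`` days, or windows containing missing temperatures)
are flagged and carry NaN so they drop out of likelihoods downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .splines import BasisSpec, ns_basis

__all__ = ["CrossBasisMatrix", "build_crossbasis", "crossbasis_prediction_vector"]


@dataclass
class CrossBasisMatrix:
    values: np.ndarray          # (n_days, vx * vl)
    exposure_spec: BasisSpec
    lag_spec: BasisSpec
    max_lag: int
    complete: np.ndarray        # (n_days,) bool; False where window incomplete

    @property
    def vx(self) -> int:
        return self.exposure_spec.dim

    @property
    def vl(self) -> int:
        return self.lag_spec.dim


def build_crossbasis(tmean, exposure_spec: BasisSpec, lag_spec: BasisSpec,
                     max_lag: int) -> CrossBasisMatrix:
    """Build the crossbasis design block for a daily temperature series.

    Lags are evaluated at the integer days ``0..max_lag`` inclusive; the
    entry for day ``t`` accumulates the exposure basis of each lagged
    temperature weighted by the lag basis at that lag.
    """
    x = np.asarray(tmean, dtype=float)
    n = len(x)
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    if n < max_lag + 1:
        raise ValueError(f"series of length {n} shorter than max_lag+1 = "
                         f"{max_lag + 1}")
    R = ns_basis(x, exposure_spec)                       # n x vx
    C = ns_basis(np.arange(max_lag + 1), lag_spec)       # (L+1) x vl
    vx, vl = R.shape[1], C.shape[1]
    acc = np.zeros((n, vx, vl))
    for lag in range(max_lag + 1):
        shifted = np.full_like(R, np.nan)
        shifted[lag:] = R[:n - lag]
        acc += shifted[:, :, None] * C[lag][None, None, :]
    values = acc.reshape(n, vx * vl)
    complete = np.isfinite(values).all(axis=1)
    return CrossBasisMatrix(values, exposure_spec, lag_spec, int(max_lag),
                            complete)


def crossbasis_prediction_vector(x, exposure_spec: BasisSpec,
                                 lag_spec: BasisSpec, max_lag: int) -> np.ndarray:
    """Overall-cumulative prediction vector(s) w(x).

    ``w_(i,j)(x) = R_i(x) * sum_l C_j(l)`` -- the crossbasis row of a day
    whose whole trailing window sat at constant temperature ``x``.  Dotting
    ``w(x) - w(ref)`` with crossbasis coefficients gives the lag-cumulated
    log relative risk of ``x`` versus ``ref``; every MMT and cRR computation
    reduces to this vector.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    R = ns_basis(np.atleast_1d(x), exposure_spec)        # m x vx
    csum = ns_basis(np.arange(max_lag + 1), lag_spec).sum(axis=0)   # vl
    W = (R[:, :, None] * csum[None, None, :]).reshape(R.shape[0], -1)
    return W[0] if scalar else W
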