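"""Assembly and fitting of the time-varying DLNM regression.

The full design for one mortality stratum is

    log E[Y_t] = a + cb(temp)_t + dow + holiday + PM10(ma lag0-2)
                 + ns(RH(ma lag0-2), 3 df) + ns(time, 10 df/year)
                 + cb(temp)_t * s_t          (time interaction, optional)

where ``s_t`` is calendar time in years, centred at the series midpoint
for numerical conditioning (all predictions are invariant to this affine
choice).  The interaction lets the exposure-lag-response surface drift
linearly in time; the surface at any centring date c is recovered from a
single fit via

    beta(c) = beta_main + s_c * beta_int
    V(c)    = V_mm + s_c^2 * V_ii + s_c * (V_mi + V_mi')

which equals a full refit with time re-centred at c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .crossbasis import build_crossbasis
from .dataio import DailySeries, get_logger
from .qpoisson import FitResult, fit_quasipoisson
from .splines import BasisSpec, ns_basis, place_exposure_knots, place_lag_knots

__all__ = ["ModelDesign", "TimeSliceCoefs", "assemble_design", "fit_tv_model",
           "coefficients_at_time"]

DAYS_PER_YEAR = 365.25


@dataclass
class ModelDesign:
    stratum: str
    X: np.ndarray                 # complete rows only
    y: np.ndarray
    blocks: dict                  # block name -> slice into columns
    col_names: list
    rows_used: np.ndarray         # bool mask over the full series
    s: np.ndarray                 # scaled time (years), full series length
    t_ref_index: float
    exposure_spec: BasisSpec
    lag_spec: BasisSpec
    series: DailySeries
    config: RunConfig

    @property
    def n_crossbasis(self) -> int:
        return self.blocks["crossbasis"].stop - self.blocks["crossbasis"].start


@dataclass
class TimeSliceCoefs:
    centre: pd.Timestamp
    beta: np.ndarray              # length vx*vl
    vcov: np.ndarray              # (vx*vl)^2


def _moving_average(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Mean of lags 0..max_lag; NaN where the window is incomplete."""
    s = pd.Series(x)
    return s.rolling(window=max_lag + 1, min_periods=max_lag + 1).mean() \
        .to_numpy()


def assemble_design(series: DailySeries, stratum: str, config: RunConfig,
                    centre_index: float = None) -> ModelDesign:
    """Build the labelled design matrix for one stratum.

    ``centre_index`` overrides the time-centring day index (default: series
    midpoint); used by the refit-equivalence identity and tests.
    """
    df = series.frame
    n = series.n
    tmean = df["tmean"].to_numpy(dtype=float)
    y_full = series.deaths(stratum)

    exposure_spec = place_exposure_knots(tmean,
                                         config.exposure_knot_percentiles)
    lag_spec = place_lag_knots(config.max_lag, config.n_lag_knots) \
        if config.max_lag >= 1 else BasisSpec("const")
    cb = build_crossbasis(tmean, exposure_spec, lag_spec, config.max_lag)
    k = cb.values.shape[1]

    # day-of-week indicators, Monday reference
    dow = df["dow"].to_numpy()
    dow_cols = np.column_stack([(dow == d).astype(float) for d in range(2, 8)])
    holiday = df["holiday"].to_numpy(dtype=float)[:, None]

    pm10_ma = _moving_average(df["pm10"].to_numpy(dtype=float),
                              config.ma_max_lag)[:, None]
    rh_ma = _moving_average(df["rh"].to_numpy(dtype=float), config.ma_max_lag)
    rh_ok = rh_ma[np.isfinite(rh_ma)]
    if rh_ok.size == 0:
        raise ValueError("all RH values missing")
    n_rh_interior = config.rh_df - 1
    rh_knots = tuple(np.percentile(
        rh_ok, np.linspace(0, 100, n_rh_interior + 2)[1:-1]))
    rh_spec = BasisSpec("ns", rh_knots, (float(rh_ok.min()), float(rh_ok.max())),
                        intercept=False)
    rh_cols = ns_basis(rh_ma, rh_spec)

    # long-term time spline: round(df_per_year * years) total df
    t_years = np.arange(n) / DAYS_PER_YEAR
    n_years = n / DAYS_PER_YEAR
    time_df = int(round(config.time_df_per_year * n_years))
    time_df = max(time_df, 2)
    interior = tuple(np.linspace(0.0, t_years[-1], time_df + 1)[1:-1])
    time_spec = BasisSpec("ns", interior, (0.0, float(t_years[-1])),
                          intercept=False)
    time_cols = ns_basis(t_years, time_spec)

    t_ref = (n - 1) / 2.0 if centre_index is None else float(centre_index)
    s = (np.arange(n) - t_ref) / DAYS_PER_YEAR

    blocks = {}
    parts = []
    names = []

    def add(name, mat, labels):
        start = sum(p.shape[1] for p in parts)
        parts.append(mat)
        blocks[name] = slice(start, start + mat.shape[1])
        names.extend(labels)

    add("intercept", np.ones((n, 1)), ["intercept"])
    add("crossbasis", cb.values,
        [f"cb_{i}_{j}" for i in range(cb.vx) for j in range(cb.vl)])
    add("dow", dow_cols, [f"dow_{d}" for d in range(2, 8)])
    add("holiday", holiday, ["holiday"])
    add("pm10", pm10_ma, ["pm10_ma"])
    add("rh", rh_cols, [f"rh_ns{i}" for i in range(rh_cols.shape[1])])
    add("time", time_cols, [f"time_ns{i}" for i in range(time_cols.shape[1])])
    if config.interaction:
        add("interaction", cb.values * s[:, None],
            [f"cbxt_{i}_{j}" for i in range(cb.vx) for j in range(cb.vl)])

    X_full = np.hstack(parts)
    rows_used = np.isfinite(X_full).all(axis=1) & np.isfinite(y_full)
    n_used = int(rows_used.sum())
    p = X_full.shape[1]
    dropped = n - n_used
    if dropped:
        get_logger().info("assemble_design[%s]: dropped %d incomplete rows",
                          stratum, dropped)
    if n_used < 5 * p:
        raise ValueError(
            f"insufficient complete rows ({n_used}) for {p} parameters "
            "(need at least 5 per parameter)")
    return ModelDesign(
        stratum=stratum, X=X_full[rows_used], y=y_full[rows_used],
        blocks=blocks, col_names=names, rows_used=rows_used, s=s,
        t_ref_index=t_ref, exposure_spec=exposure_spec, lag_spec=lag_spec,
        series=series, config=config)


def fit_tv_model(design: ModelDesign) -> FitResult:
    """Fit the assembled design by quasi-Poisson IRLS."""
    return fit_quasipoisson(design.y, design.X, col_names=design.col_names)


def coefficients_at_time(fit: FitResult, design: ModelDesign,
                         centre) -> TimeSliceCoefs:
    """Crossbasis coefficients and covariance at a centring date.

    With the interaction block present, the surface at date c has
    coefficients ``beta_main + s_c * beta_int`` where ``s_c`` is the scaled
    time at c; the covariance combines the main, interaction and cross
    blocks of the joint covariance accordingly.  Without an interaction the
    slice is time-invariant.
    """
    centre = pd.Timestamp(centre)
    dates = design.series.dates
    lo, hi = dates.iloc[0], dates.iloc[-1]
    if not (lo <= centre <= hi):
        raise ValueError(f"centre {centre.date()} outside series range "
                         f"{lo.date()}..{hi.date()}")
    idx = int((centre - lo).days)
    s_c = design.s[idx]
    m = design.blocks["crossbasis"]
    beta_m = fit.coefficients[m]
    V = fit.covariance
    if "interaction" in design.blocks:
        i = design.blocks["interaction"]
        beta_i = fit.coefficients[i]
        V_mm = V[m, m]
        V_ii = V[i, i]
        V_mi = V[m, i]
        beta = beta_m + s_c * beta_i
        vcov = V_mm + s_c ** 2 * V_ii + s_c * (V_mi + V_mi.T)
    else:
        beta = beta_m.copy()
        vcov = V[m, m].copy()
    vcov = 0.5 * (vcov + vcov.T)
    return TimeSliceCoefs(centre=centre, beta=beta, vcov=vcov)
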