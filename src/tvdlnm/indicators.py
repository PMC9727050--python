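"""Adaptation indicators: cumulative RR curves, MMTs, annual anchors.

The lag-cumulated relative risk at temperature x versus a reference is
``exp((w(x) - w(ref))' beta)`` with w the overall-cumulative crossbasis
prediction vector.  The minimum mortality temperature (MMT) is the argmin
of the cumulated curve over a fine grid restricted to the central
percentiles of the exposure distribution (percentile-constricted MMT); its
uncertainty comes from a parametric bootstrap that redraws coefficient
vectors from their multivariate normal sampling distribution and relocates
the argmin for each draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .crossbasis import crossbasis_prediction_vector
from .splines import BasisSpec
from .tvmodel import ModelDesign, TimeSliceCoefs, coefficients_at_time

__all__ = ["CurvePrediction", "MMTEstimate", "AnnualIndicators",
           "predict_curve", "find_mmt", "annual_indicators",
           "temperature_trends"]

Z95 = 1.959963984540054


@dataclass
class CurvePrediction:
    grid: np.ndarray
    log_crr: np.ndarray
    se: np.ndarray
    reference: float

    @property
    def crr(self) -> np.ndarray:
        return np.exp(self.log_crr)

    @property
    def crr_low(self) -> np.ndarray:
        return np.exp(self.log_crr - Z95 * self.se)

    @property
    def crr_high(self) -> np.ndarray:
        return np.exp(self.log_crr + Z95 * self.se)


@dataclass
class MMTEstimate:
    mmt: float
    eci_low: float
    eci_high: float
    se: float
    n_boot: int
    constrained_range: tuple
    boundary_dominated: bool = False
    outside_eci: bool = False


@dataclass
class AnnualIndicators:
    year: int
    amt: float
    p1: float
    p10: float
    p90: float
    p99: float
    mmt: MMTEstimate
    crr: dict            # anchor name -> (estimate, low, high)


def _pred_matrix(x, slice_like, exposure_spec, lag_spec, max_lag):
    return crossbasis_prediction_vector(x, exposure_spec, lag_spec, max_lag)


def predict_curve(tslice: TimeSliceCoefs, grid, reference: float,
                  exposure_spec: BasisSpec, lag_spec: BasisSpec,
                  max_lag: int) -> CurvePrediction:
    """Lag-cumulated RR curve over a temperature grid, centred at ``reference``."""
    grid = np.asarray(grid, dtype=float)
    if not grid.min() <= reference <= grid.max():
        raise ValueError(f"reference {reference} outside grid range "
                         f"[{grid.min()}, {grid.max()}]")
    a, b = exposure_spec.boundary_knots
    margin = 0.10 * (b - a)
    if grid.min() < a - margin or grid.max() > b + margin:
        warnings.warn("temperature grid extends more than 10% beyond the "
                      "basis boundary knots; extrapolated risks are unstable")
    W = _pred_matrix(grid, tslice, exposure_spec, lag_spec, max_lag)
    w_ref = _pred_matrix(float(reference), tslice, exposure_spec, lag_spec,
                         max_lag)
    D = W - w_ref[None, :]
    log_crr = D @ tslice.beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", D, tslice.vcov, D), 0.0))
    return CurvePrediction(grid=grid, log_crr=log_crr, se=se,
                           reference=float(reference))


def _mvn_sqrt(vcov: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root (eigendecomposition, clipped)."""
    vals, vecs = np.linalg.eigh(vcov)
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)[None, :]


def find_mmt(tslice: TimeSliceCoefs, tmean_subset, config: RunConfig,
             exposure_spec: BasisSpec, lag_spec: BasisSpec,
             rng: np.random.Generator) -> MMTEstimate:
    """Percentile-constricted MMT with parametric-bootstrap eCI and SE.

    The search grid spans the configured constriction percentiles (defaults
    1st-99th) of ``tmean_subset`` in steps of ``config.mmt_grid_step``.  The
    point estimate is the argmin of the cumulated log-RR under the slice
    coefficients (reference-invariant); ``config.n_boot`` multivariate
    normal coefficient draws give the empirical 95% interval and SE.
    """
    t = np.asarray(tmean_subset, dtype=float)
    t = t[np.isfinite(t)]
    p_lo, p_hi = np.percentile(t, config.mmt_constraint)
    # grid aligned to absolute multiples of the step, so narrower and wider
    # constraint windows search nested grids
    step = config.mmt_grid_step
    grid = np.arange(np.ceil(p_lo / step), np.floor(p_hi / step) + 0.5) * step
    W = _pred_matrix(grid, tslice, exposure_spec, lag_spec, config.max_lag)
    log_crr = W @ tslice.beta
    if np.ptp(log_crr) < 1e-12:
        raise ValueError("MMT undefined: cumulated risk curve is flat over "
                         "the constrained range")
    mmt = float(grid[int(np.argmin(log_crr))])

    A = _mvn_sqrt(tslice.vcov)
    z = rng.standard_normal((config.n_boot, len(tslice.beta)))
    draws = tslice.beta[None, :] + z @ A.T
    curves = draws @ W.T                       # n_boot x n_grid
    arg = np.argmin(curves, axis=1)
    mmts = grid[arg]
    eci_low, eci_high = np.percentile(mmts, [2.5, 97.5])
    se = float(np.std(mmts, ddof=1)) if config.n_boot > 1 else 0.0
    boundary_frac = float(np.mean((arg == 0) | (arg == len(grid) - 1)))
    return MMTEstimate(
        mmt=mmt, eci_low=float(eci_low), eci_high=float(eci_high), se=se,
        n_boot=config.n_boot, constrained_range=(float(p_lo), float(p_hi)),
        boundary_dominated=boundary_frac > 0.5,
        outside_eci=not (eci_low <= mmt <= eci_high))


def _crr_at(x: float, reference: float, tslice: TimeSliceCoefs,
            exposure_spec, lag_spec, max_lag):
    d = (_pred_matrix(float(x), tslice, exposure_spec, lag_spec, max_lag)
         - _pred_matrix(float(reference), tslice, exposure_spec, lag_spec,
                        max_lag))
    log_crr = float(d @ tslice.beta)
    se = float(np.sqrt(max(d @ tslice.vcov @ d, 0.0)))
    return (np.exp(log_crr), np.exp(log_crr - Z95 * se),
            np.exp(log_crr + Z95 * se))


def annual_indicators(fit, design: ModelDesign, year: int,
                      rng: np.random.Generator) -> AnnualIndicators:
    """Year-specific MMT and cRR anchors for one stratum.

    Percentile anchors and the AMT come from that calendar year's observed
    daily means (configurable to the full period); the coefficient slice is
    taken at the annual centring date (1 July by default), and the cRR
    curve is re-centred at the year's MMT.
    """
    config = design.config
    df = design.series.frame
    in_year = df["date"].dt.year == year
    if not in_year.any():
        raise ValueError(f"year {year} not in series")
    t_year = df.loc[in_year, "tmean"].to_numpy(dtype=float)
    if np.mean(~np.isfinite(t_year)) > 0.20:
        raise ValueError(f"year {year}: more than 20% of temperatures missing")
    t_year = t_year[np.isfinite(t_year)]
    if config.annual_percentile_basis == "period":
        t_anchor = df["tmean"].to_numpy(dtype=float)
        t_anchor = t_anchor[np.isfinite(t_anchor)]
    else:
        t_anchor = t_year
    pcts = {name: float(np.percentile(t_anchor, p))
            for name, p in config.anchor_percentiles.items()}
    amt = float(np.mean(t_year))

    centre = pd.Timestamp(year=year, month=config.centre_month,
                          day=config.centre_day)
    tslice = coefficients_at_time(fit, design, centre)
    mmt = find_mmt(tslice, t_anchor, config, design.exposure_spec,
                   design.lag_spec, rng)
    crr = {name: _crr_at(pcts[name], mmt.mmt, tslice, design.exposure_spec,
                         design.lag_spec, config.max_lag)
           for name in ("extreme_cold", "moderate_cold", "moderate_heat",
                        "extreme_heat")}
    return AnnualIndicators(
        year=int(year), amt=amt,
        p1=pcts["extreme_cold"], p10=pcts["moderate_cold"],
        p90=pcts["moderate_heat"], p99=pcts["extreme_heat"],
        mmt=mmt, crr=crr)


def temperature_trends(series, config: RunConfig = None) -> pd.DataFrame:
    """Annual AMT / P1 / P99 and their OLS linear trends against year.

    Returns a table with one row per indicator carrying slope, t statistic
    and p-value, plus per-year values in the attached ``.attrs['annual']``
    frame.
    """
    df = series.frame
    years = sorted(df["date"].dt.year.unique())
    if len(years) < 3:
        raise ValueError("need at least 3 calendar years for a trend")
    rows = []
    for y in years:
        t = df.loc[df["date"].dt.year == y, "tmean"].to_numpy(dtype=float)
        t = t[np.isfinite(t)]
        rows.append({"year": y, "amt": np.mean(t),
                     "p1": np.percentile(t, 1.0),
                     "p99": np.percentile(t, 99.0)})
    annual = pd.DataFrame(rows)
    out = []
    for col in ("amt", "p1", "p99"):
        res = stats.linregress(annual["year"], annual[col])
        tstat = res.slope / res.stderr if res.stderr > 0 else 0.0
        out.append({"indicator": col, "slope": res.slope,
                    "intercept": res.intercept, "t_statistic": tstat,
                    "p_value": res.pvalue if res.stderr > 0 else 1.0})
    table = pd.DataFrame(out)
    table.attrs["annual"] = annual
    return table
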