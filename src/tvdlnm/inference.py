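"""Formal tests: interaction Wald test, WLS trends, coupling, chi-square.

The multivariate Wald statistic ``W = b' V^-1 b`` on the interaction block
tests the null of a time-constant exposure-lag-response surface against
chi-square with df equal to the number of interaction coefficients.  Trend
regressions of annual indicators on year use inverse-variance weighted
least squares (weights 1/se^2), with R^2, the Snedecor F statistic and the
unweighted Pearson correlation reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .dataio import get_logger
from .qpoisson import FitResult
from .tvmodel import ModelDesign

__all__ = ["WaldResult", "TrendResult", "wald_interaction_test", "wls_trend",
           "coupling_regression", "missingness_chisq"]

ALPHA = 0.05


@dataclass
class WaldResult:
    statistic: float
    df: int
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass
class TrendResult:
    slope: float
    intercept: float
    slope_se: float
    r_squared: float
    f_statistic: float
    p_value: float
    pearson_r: float
    weights: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)
    fitted: np.ndarray = field(repr=False, default=None)

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def wald_interaction_test(fit: FitResult, design: ModelDesign) -> WaldResult:
    """Multivariate Wald test that all interaction coefficients are zero."""
    if "interaction" not in design.blocks:
        raise ValueError("model has no interaction block")
    idx = design.blocks["interaction"]
    beta = fit.coefficients[idx]
    V = fit.covariance[idx, idx]
    cond = np.linalg.cond(V)
    if cond < 1e10:
        W = float(beta @ np.linalg.solve(V, beta))
    else:
        get_logger().warning(
            "interaction covariance near-singular (cond=%.2e); using "
            "pseudo-inverse", cond)
        W = float(beta @ np.linalg.pinv(V) @ beta)
    W = max(W, 0.0)
    df = len(beta)
    return WaldResult(statistic=W, df=df, p_value=float(stats.chi2.sf(W, df)))


def wls_trend(years, values, ses=None) -> TrendResult:
    """Inverse-variance weighted linear regression of an indicator on year.

    Observations with larger standard errors are down-weighted
    (weights 1/se^2); with ``ses`` absent all weights are equal and the fit
    reduces to OLS exactly.
    """
    x = np.asarray(years, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points for a trend regression")
    if np.ptp(x) == 0:
        raise ValueError("regressor is constant")
    if ses is None:
        w = np.ones_like(y)
    else:
        ses = np.asarray(ses, dtype=float)
        if np.any(~(ses > 0)):
            raise ValueError("standard errors must be positive")
        w = 1.0 / ses ** 2
    X = sm.add_constant(x)
    res = sm.WLS(y, X, weights=w).fit()
    if np.ptp(y) == 0:
        pearson = 0.0
    else:
        pearson = float(np.corrcoef(x, y)[0, 1])
    fvalue = float(res.fvalue) if np.isfinite(res.fvalue) else 0.0
    pval = float(res.pvalues[1]) if np.isfinite(res.pvalues[1]) else 1.0
    return TrendResult(
        slope=float(res.params[1]), intercept=float(res.params[0]),
        slope_se=float(res.bse[1]),
        r_squared=float(np.clip(res.rsquared, 0.0, 1.0)),
        f_statistic=fvalue, p_value=pval, pearson_r=pearson,
        weights=w, residuals=np.asarray(res.resid),
        fitted=np.asarray(res.fittedvalues))


def coupling_regression(x, y, y_ses=None) -> TrendResult:
    """WLS regression of one annual indicator on another (e.g. MMT on AMT)."""
    return wls_trend(x, y, y_ses)


def missingness_chisq(table) -> tuple:
    """Pearson chi-square on a missing-vs-present contingency table.

    Returns ``(statistic, df, p_value)``; df = (rows-1)(cols-1).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need a 2-d contingency table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero marginal")
    stat, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), int(df), float(p)
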