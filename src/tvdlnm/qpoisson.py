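"""Quasi-Poisson regression by iteratively reweighted least squares.

Overdispersed daily death counts are modelled with a log-link Poisson mean
structure and a free dispersion parameter phi estimated from the Pearson
statistic; the coefficient covariance is the Fisher-information inverse
scaled by phi.  Model comparison uses qAIC, the quasi-likelihood analogue
of AIC, with the model's own dispersion estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve, qr
from scipy.special import gammaln

__all__ = ["FitResult", "fit_quasipoisson", "qaic"]


@dataclass
class FitResult:
    """One converged quasi-Poisson fit.

    ``covariance`` is dispersion-scaled: ``phi * (X'WX)^-1`` at the MLE.
    ``poisson_loglik`` is the ordinary Poisson log-likelihood at the MLE
    (the quantity qAIC rescales by the dispersion).
    """

    coefficients: np.ndarray
    covariance: np.ndarray
    dispersion: float
    poisson_loglik: float
    n_obs: int
    n_params: int
    converged: bool
    col_names: list = field(default_factory=list)
    fitted: np.ndarray = None
    deviance: float = np.nan
    unscaled_covariance: np.ndarray = None


def _poisson_deviance(y, mu):
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return 2.0 * np.sum(term - (y - mu))


def _diagnose_collinearity(X, col_names):
    _, R, piv = qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    tol = d.max() * max(X.shape) * np.finfo(float).eps
    bad = piv[np.sum(d > tol):]
    names = [col_names[j] if col_names else f"col{j}" for j in sorted(bad)]
    return names


def fit_quasipoisson(y, X, col_names=None, tol=1e-9, max_iter=100) -> FitResult:
    """Fit a log-link quasi-Poisson regression.

    Parameters
    ----------
    y : array of non-negative integer counts.
    X : design matrix, full column rank on the rows supplied (rows with
        missing entries must be excluded beforehand).
    col_names : optional labels used in error messages and block slicing.

    Notes
    -----
    IRLS iterates weighted least squares on the working response until the
    relative deviance change falls below ``tol`` (default 1e-9, at most
    ``max_iter`` iterations), then takes one extra polishing step so that
    coefficient-level identities hold to tighter tolerance than the deviance
    stopping rule alone guarantees.  Dispersion is the Pearson chi-square
    over residual degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.ndim != 1 or X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("y and X have incompatible shapes")
    if np.any(~np.isfinite(y)) or np.any(~np.isfinite(X)):
        raise ValueError("y and X must be finite (drop missing rows first)")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("y must contain non-negative integer counts")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n_obs ({n}) must exceed n_params ({p})")
    col_names = list(col_names) if col_names is not None else []

    mu = y + 0.5
    eta = np.log(mu)
    dev = _poisson_deviance(y, mu)
    beta = None
    trace = []
    converged = False
    polish = 0
    for it in range(max_iter):
        w = mu
        z = eta + (y - mu) / mu
        Xw = X * w[:, None]
        A = X.T @ Xw
        b = Xw.T @ z
        try:
            cf = cho_factor(A, check_finite=False)
        except LinAlgError:
            bad = _diagnose_collinearity(X, col_names)
            raise ValueError(
                "design matrix is rank deficient; collinear columns involve: "
                f"{bad}") from None
        beta_new = cho_solve(cf, b, check_finite=False)
        eta_new = X @ beta_new
        # step-halving safeguard against overshoot in early iterations
        step = 1.0
        for _ in range(8):
            mu_new = np.exp(np.clip(eta_new, None, 500.0))
            dev_new = _poisson_deviance(y, mu_new)
            if (np.isfinite(dev_new) and eta_new.max() < 500.0
                    and (dev_new <= dev + 1e-8 or beta is None)):
                break
            step /= 2.0
            beta_new = beta + step * (beta_new - beta) if beta is not None \
                else beta_new * step
            eta_new = X @ beta_new
        beta, eta, mu = beta_new, eta_new, mu_new
        rel = abs(dev - dev_new) / (abs(dev_new) + 0.1)
        trace.append((it, dev_new, rel))
        dev = dev_new
        if rel < tol:
            if polish >= 1:
                converged = True
                break
            polish += 1
    if not converged:
        raise RuntimeError(
            f"IRLS failed to converge in {max_iter} iterations; trace tail: "
            f"{trace[-5:]}")

    w = mu
    A = X.T @ (X * w[:, None])
    cf = cho_factor(A, check_finite=False)
    unscaled = cho_solve(cf, np.eye(p), check_finite=False)
    unscaled = 0.5 * (unscaled + unscaled.T)
    pearson = np.sum((y - mu) ** 2 / mu)
    phi = pearson / (n - p)
    with np.errstate(divide="ignore"):
        ll = np.sum(y * eta - mu - gammaln(y + 1.0))
    return FitResult(
        coefficients=beta,
        covariance=phi * unscaled,
        dispersion=float(phi),
        poisson_loglik=float(ll),
        n_obs=n,
        n_params=p,
        converged=True,
        col_names=col_names,
        fitted=mu,
        deviance=float(dev),
        unscaled_covariance=unscaled,
    )


def qaic(fit: FitResult, dispersion: float = None) -> float:
    """qAIC = -2 * loglik / phi + 2 * n_params (lower is better).

    By default phi is the fit's own Pearson dispersion.  When ranking a set
    of candidate models pass a common ``dispersion`` (conventionally the
    estimate from the most complex candidate): with per-model dispersions a
    poorly fitting model inflates its own phi and thereby *deflates* its
    qAIC, which can invert the ranking.
    """
    phi = fit.dispersion if dispersion is None else float(dispersion)
    if not phi > 0:
        raise ValueError("degenerate fit: dispersion must be positive")
    return -2.0 * fit.poisson_loglik / phi + 2.0 * fit.n_params
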