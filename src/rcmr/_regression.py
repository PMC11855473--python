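"""Closed-form least-squares and logistic helpers shared across the pipeline.

The per-variant association scans that dominate the Monte-Carlo harnesses are
plain OLS with a covariate design that is identical for every variant, so they
are computed by the Frisch-Waugh-Lovell route: residualize the trait and every
dosage column on the covariates once, then finish each single-variant model
with two dot products.  This is algebraically exact OLS for the full model
``trait ~ covariates + dosage`` (tested against the normal equations at 1e-10),
not an approximation.

Logistic fits go through :mod:`statsmodels`; non-convergence and perfect
separation are converted into :class:`~rcmr.exceptions.ConvergenceError`
instead of being silently returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .exceptions import ConvergenceError

__all__ = [
    "OLSFit",
    "LogitFit",
    "add_intercept",
    "ols",
    "logit",
    "residualize",
    "variant_scan",
]


@dataclass
class OLSFit:
    """Ordinary-least-squares fit: coefficients with Wald inference."""

    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    df_resid: int
    sigma2: float
    fitted: np.ndarray
    resid: np.ndarray

    def coef(self, j: int) -> tuple[float, float, float]:
        """(beta, se, p) for column ``j`` of the design."""
        return float(self.beta[j]), float(self.se[j]), float(self.p[j])


@dataclass
class LogitFit:
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    converged: bool
    llf: float

    def coef(self, j: int) -> tuple[float, float, float]:
        return float(self.beta[j]), float(self.se[j]), float(self.p[j])


def add_intercept(X: np.ndarray | None, n: int | None = None) -> np.ndarray:
    """Prepend a column of ones; ``X=None`` yields an intercept-only design."""
    if X is None:
        if n is None:
            raise ValueError("n required when X is None")
        return np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([np.ones(len(X)), X])


def ols(X: np.ndarray, y: np.ndarray) -> OLSFit:
    """Exact OLS of ``y`` on ``X`` (X must already contain any intercept).

    Standard errors use the unbiased residual variance with
    ``df = n - rank(X)``; p values are two-sided t.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError as exc:  # singular design
        raise np.linalg.LinAlgError(f"singular design matrix ({n}x{k})") from exc
    beta = XtX_inv @ Xty
    fitted = X @ beta
    resid = y - fitted
    df = n - k
    if df <= 0:
        raise ValueError(f"no residual degrees of freedom (n={n}, k={k})")
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return OLSFit(beta=beta, se=se, p=p, df_resid=df, sigma2=sigma2, fitted=fitted, resid=resid)


def logit(X: np.ndarray, y: np.ndarray, maxiter: int = 200) -> LogitFit:
    """Maximum-likelihood logistic regression with explicit failure reporting."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.isin(np.unique(y), (0.0, 1.0)).all():
        raise ValueError("logistic outcome must be coded 0/1")
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=maxiter, method="newton")
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
        raise ConvergenceError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError("logistic fit did not converge")
    bse = np.asarray(res.bse)
    if not np.all(np.isfinite(bse)):
        raise ConvergenceError("logistic fit produced non-finite standard errors (separation?)")
    return LogitFit(
        beta=np.asarray(res.params),
        se=bse,
        p=np.asarray(res.pvalues),
        converged=True,
        llf=float(res.llf),
    )


def residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of each column of ``M`` after projecting out ``C``.

    Uses a QR-based least-squares projection, so rank-deficient covariate
    designs are handled.
    """
    M = np.asarray(M, dtype=float)
    coef, *_ = np.linalg.lstsq(C, M, rcond=None)
    return M - C @ coef


def variant_scan(
    G: np.ndarray,
    y: np.ndarray,
    C: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column OLS of ``y ~ C + G[:, j]`` for every j, vectorized.

    Parameters
    ----------
    G : (n, m) dosage (or any predictor) matrix.
    y : (n,) trait vector.
    C : (n, p) covariate design including the intercept column.

    Returns
    -------
    (beta, se, p) arrays of length m.  Monomorphic-after-adjustment columns
    yield NaN rather than raising, so callers can filter.
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p_cov = C.shape
    coef, *_ = np.linalg.lstsq(C, np.column_stack([G, y]), rcond=None)
    R = np.column_stack([G, y]) - C @ coef
    Gt, yt = R[:, :-1], R[:, -1]
    gg = np.einsum("ij,ij->j", Gt, Gt)
    gy = Gt.T @ yt
    yy = float(yt @ yt)
    df = n - p_cov - 1
    if df <= 0:
        raise ValueError("no residual degrees of freedom in scan")
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(gg > 0, gy / np.where(gg > 0, gg, 1.0), np.nan)
        rss = yy - beta**2 * gg
        sigma2 = np.maximum(rss, 0.0) / df
        se = np.where(gg > 0, np.sqrt(sigma2 / np.where(gg > 0, gg, 1.0)), np.nan)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, se, p
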