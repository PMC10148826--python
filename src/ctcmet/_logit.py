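"""Maximum-likelihood logistic fits with a ridge-penalized fallback.

statsmodels' Logit is the primary route; when it hits complete separation
or fails to converge, a small-ridge Newton fit supplies finite
coefficients and a Wald covariance from the penalized Hessian, and the
result is flagged so callers can warn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationError


@dataclass
class LogitFit:
    params: np.ndarray
    bse: np.ndarray
    p_values: np.ndarray
    cov: np.ndarray
    flagged: bool  # True when the penalized fallback was used


def _ridge_logit(y: np.ndarray, X: np.ndarray, alpha: float = 1.0) -> LogitFit:
    """Newton-Raphson logistic regression with an L2 penalty on all terms."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(200):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - alpha * beta
        H = X.T @ (X * w[:, None]) + alpha * np.eye(p)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    H = X.T @ (X * w[:, None]) + alpha * np.eye(p)
    cov = np.linalg.inv(H)
    bse = np.sqrt(np.diag(cov))
    from scipy import stats

    z = beta / bse
    pvals = 2 * stats.norm.sf(np.abs(z))
    return LogitFit(params=beta, bse=bse, p_values=pvals, cov=cov, flagged=True)


def fit_logit(y, X, add_const: bool = True) -> LogitFit:
    """ML logistic regression of binary ``y`` on ``X``.

    Returns natural-log-scale coefficients with Wald standard errors and
    p-values. The first parameter is the intercept when ``add_const``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    design = sm.add_constant(X, has_constant="add") if add_const else X
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            warnings.simplefilter("error", RuntimeWarning)
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", False) or not np.all(
            np.isfinite(res.bse)
        ):
            raise PerfectSeparationError("non-finite standard errors")
        return LogitFit(
            params=np.asarray(res.params),
            bse=np.asarray(res.bse),
            p_values=np.asarray(res.pvalues),
            cov=np.asarray(res.cov_params()),
            flagged=False,
        )
    except (PerfectSeparationError, ConvergenceWarning, RuntimeWarning,
            np.linalg.LinAlgError, ValueError):
        return _ridge_logit(y, design)
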