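"""Small dense GLM fits for the resampling hot loops.

Permutation and bootstrap tests of a path-specific effect re-estimate every
per-edge regression hundreds of thousands of times on designs with a handful
of columns.  These routines do exactly that job on plain numpy arrays: OLS via
the normal equations and logistic regression via Newton/IRLS, each returning
the coefficient vector and its covariance.  They are cross-checked against
statsmodels in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


class FitError(RuntimeError):
    """A regression could not be fit (rank deficiency, separation, ...)."""


class CollinearityError(FitError):
    """Design matrix is rank deficient."""


def ols_fit(X: np.ndarray, y: np.ndarray, check_rank: bool = True):
    """Least squares of y on X (X includes the intercept column).

    Returns (beta, cov, sigma2).  Raises CollinearityError if X is rank
    deficient.
    """
    n, p = X.shape
    xtx = X.T @ X
    if check_rank:
        rank = np.linalg.matrix_rank(xtx)
        if rank < p:
            raise CollinearityError(
                f"design matrix has rank {rank} < {p} columns"
            )
    xty = X.T @ y
    try:
        beta = np.linalg.solve(xtx, xty)
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise CollinearityError(str(exc)) from exc
    resid = y - X @ beta
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * xtx_inv
    return beta, cov, sigma2


_ETA_CLIP = 30.0


def logistic_fit(
    X: np.ndarray,
    y: np.ndarray,
    beta0: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-9,
    ridge: float = 1e-9,
):
    """Newton/IRLS logistic regression.

    X includes the intercept column; y is 0/1.  Returns (beta, cov) with cov
    the inverse observed Fisher information.  A tiny ridge stabilises the
    Newton step; linear predictors are clipped at +/-30 so quasi-separated
    resamples converge to a finite (clipped) solution instead of diverging.
    """
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else np.array(beta0, dtype=float)
    H = None
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = expit(eta)
        w = mu * (1.0 - mu) + 1e-12
        g = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        H[np.diag_indices_from(H)] += ridge
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise CollinearityError(str(exc)) from exc
        # dampen huge steps (separation)
        norm = np.max(np.abs(step))
        if norm > 10.0:
            step *= 10.0 / norm
        beta += step
        if norm < tol:
            break
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise CollinearityError(str(exc)) from exc
    return beta, cov


def logistic_fit_weighted(
    X: np.ndarray,
    n_success: np.ndarray,
    n_total: np.ndarray,
    beta0: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-9,
    ridge: float = 1e-9,
):
    """Binomial IRLS over unique covariate patterns with counts.

    Equivalent to :func:`logistic_fit` on the expanded rows: X holds one row
    per pattern, n_success successes out of n_total trials per pattern.
    Zero-count patterns are carried with weight zero.
    """
    p = X.shape[1]
    beta = np.zeros(p) if beta0 is None else np.array(beta0, dtype=float)
    H = None
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = expit(eta)
        w = n_total * mu * (1.0 - mu) + 1e-12
        g = X.T @ (n_success - n_total * mu)
        H = (X * w[:, None]).T @ X
        H[np.diag_indices_from(H)] += ridge
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise CollinearityError(str(exc)) from exc
        norm = np.max(np.abs(step))
        if norm > 10.0:
            step *= 10.0 / norm
        beta += step
        if norm < tol:
            break
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise CollinearityError(str(exc)) from exc
    return beta, cov


def standardized_risk_difference_weighted(
    X: np.ndarray,
    weights: np.ndarray,
    beta: np.ndarray,
    cov: np.ndarray,
    a_col: int,
    x_hi: float,
    x_lo: float,
):
    """Pattern-weighted version of :func:`standardized_risk_difference`."""
    total = weights.sum()
    Xh = X.copy()
    Xh[:, a_col] = x_hi
    Xl = X.copy()
    Xl[:, a_col] = x_lo
    mh = expit(np.clip(Xh @ beta, -_ETA_CLIP, _ETA_CLIP))
    ml = expit(np.clip(Xl @ beta, -_ETA_CLIP, _ETA_CLIP))
    est = float(weights @ (mh - ml) / total)
    gh = (Xh * (weights * mh * (1.0 - mh))[:, None]).sum(axis=0) / total
    gl = (Xl * (weights * ml * (1.0 - ml))[:, None]).sum(axis=0) / total
    g = gh - gl
    var = float(g @ cov @ g)
    return est, max(var, 0.0)


def standardized_risk_difference(
    X: np.ndarray,
    beta: np.ndarray,
    cov: np.ndarray,
    a_col: int,
    x_hi: float,
    x_lo: float,
):
    """Model-based standardization of a fitted logistic child model.

    Averages P(child=1 | A=x_hi, C) - P(child=1 | A=x_lo, C) over the
    empirical covariate rows in X, i.e. sum_c [P(B|x', c) - P(B|x'', c)] P(c)
    with the stratum probabilities replaced by the empirical distribution.
    Returns (estimate, variance) with the variance from the delta method in
    the model coefficients (the covariate distribution is treated as fixed).
    """
    Xh = X.copy()
    Xh[:, a_col] = x_hi
    Xl = X.copy()
    Xl[:, a_col] = x_lo
    mh = expit(np.clip(Xh @ beta, -_ETA_CLIP, _ETA_CLIP))
    ml = expit(np.clip(Xl @ beta, -_ETA_CLIP, _ETA_CLIP))
    est = float(mh.mean() - ml.mean())
    gh = (Xh * (mh * (1.0 - mh))[:, None]).mean(axis=0)
    gl = (Xl * (ml * (1.0 - ml))[:, None]).mean(axis=0)
    g = gh - gl
    var = float(g @ cov @ g)
    return est, max(var, 0.0)
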