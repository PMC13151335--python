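"""Shared least-squares helpers.

All association stages reduce to OLS with a common covariate block, so the
heavy lifting is done once here: building design matrices, residualizing
against covariates (Frisch-Waugh), and vectorized per-gene / per-variant
slope tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def design_matrix(covariates: pd.DataFrame | None, n: int,
                  add_intercept: bool = True) -> np.ndarray:
    """Covariate design matrix with optional intercept; checks full rank."""
    blocks = []
    if add_intercept:
        blocks.append(np.ones((n, 1)))
    if covariates is not None and covariates.shape[1] > 0:
        X = covariates.to_numpy(dtype=float)
        if X.shape[0] != n:
            raise ValueError("covariate rows do not match sample count")
        blocks.append(X)
    X = np.hstack(blocks)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _collinear_columns(X, covariates, add_intercept)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return X


def _collinear_columns(X, covariates, add_intercept):
    names = (["intercept"] if add_intercept else []) + (
        list(covariates.columns) if covariates is not None else []
    )
    bad = []
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
            bad.append(names[j] if j < len(names) else f"col{j}")
    return bad


def residualize(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of each column (or the vector) of Y against X."""
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return Y - X @ coef


def ols_fit(y: np.ndarray, X: np.ndarray):
    """Plain OLS: returns (coefs, se, t, p, rss, df)."""
    n, k = X.shape
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = n - k
    rss = float(resid @ resid)
    sigma2 = rss / df
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    t = coef / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return coef, se, t, p, rss, df


def marginal_slope_tests(Y: np.ndarray, G: np.ndarray, X: np.ndarray,
                         df_adjust: int | None = None):
    """Vectorized slope tests of each column of Y on each column of G given X.

    Y (n x q) and G (n x m) are first residualized against the common
    covariate matrix X; the slope, SE, t and p of every (q x m) pair then
    follow from the residual cross-products, with the residual degrees of
    freedom ``n - X.shape[1] - 1`` (Frisch-Waugh equivalence with the joint
    multiple regression).
    """
    n = Y.shape[0]
    Yr = residualize(Y, X)
    Gr = residualize(G, X)
    df = n - X.shape[1] - 1 if df_adjust is None else df_adjust
    gss = np.sum(Gr ** 2, axis=0)  # m
    gss_safe = np.where(gss <= 0, np.nan, gss)
    cross = Yr.T @ Gr  # q x m
    beta = cross / gss_safe[None, :]
    yss = np.sum(Yr ** 2, axis=0)  # q
    rss = yss[:, None] - beta * cross
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / df
    se = np.sqrt(sigma2 / gss_safe[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta, se, t, p, df


def incremental_r2(y: np.ndarray, X_cov: np.ndarray, extra: np.ndarray):
    """R2 gain of adding ``extra`` columns to the covariate model.

    Returns (delta_r2, p) where p is the F-test p-value for the added block
    (t-test when a single column is added).
    """
    extra = np.atleast_2d(extra.T).T if extra.ndim == 1 else extra
    y = np.asarray(y, dtype=float)
    tss = float(np.sum((y - y.mean()) ** 2))
    _, _, _, _, rss0, _ = ols_fit(y, X_cov)
    X_full = np.hstack([X_cov, extra])
    _, _, _, _, rss1, df1 = ols_fit(y, X_full)
    delta = (rss0 - rss1) / tss if tss > 0 else 0.0
    q = extra.shape[1]
    if rss1 <= 0 or df1 <= 0:
        return max(delta, 0.0), np.nan
    f = ((rss0 - rss1) / q) / (rss1 / df1)
    p = stats.f.sf(f, q, df1) if f > 0 else 1.0
    return max(delta, 0.0), float(p)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, monotone)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
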