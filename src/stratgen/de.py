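"""Covariate-adjusted pseudobulk differential expression and set overlap.

The DE model is per-gene least squares of log-CPM on the tested outcome plus
covariates, with an optional voom-style precision weight derived from the
mean-variance trend.  This is a plain (or precision-weighted) OLS rather
than an empirical-Bayes moderated fit; with pseudobulk sample sizes in the
tens the moderation has little effect and the unmoderated t keeps the
estimator transparent and exactly testable against a normal-equations
oracle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .regression import bh_fdr, design_matrix

try:  # statsmodels lowess for the voom-like trend
    from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess
except ImportError:  # pragma: no cover
    _lowess = None


def de_test(
    expr,
    outcome,
    covariates: pd.DataFrame | None = None,
    weights: str = "none",
    exclude_genes: list | None = None,
) -> pd.DataFrame:
    """Per-gene association of expression with one outcome.

    Parameters
    ----------
    expr : NormalizedExpression or DataFrame
        Genes x individuals log-CPM (or otherwise normalized) values.
    outcome : array-like
        Per-individual outcome (continuous outcomes should be
        inverse-normal transformed upstream where the protocol requires it).
    covariates : DataFrame, optional
        Per-individual covariates (the tested outcome must not be among them).
    weights : {"none", "voom"}
        "voom" fits a lowess trend of sqrt residual SD on mean log-count and
        uses the inverse squared fitted trend as precision weights.
    exclude_genes : list, optional
        Genes removed before testing (e.g. sex-chromosome genes when the
        outcome is sex).

    Returns
    -------
    DataFrame with columns gene, beta, t, p, q, direction.
    """
    values = expr.values if hasattr(expr, "values") and isinstance(getattr(expr, "values"), pd.DataFrame) else expr
    values = pd.DataFrame(values)
    if exclude_genes:
        values = values.drop(index=[g for g in exclude_genes if g in values.index])
    y = np.asarray(outcome, dtype=float)
    n = values.shape[1]
    if y.shape[0] != n:
        raise ValueError("outcome length does not match individuals")
    X = design_matrix(covariates, n)  # validates rank, names collinear columns
    X = np.hstack([X, y[:, None]])
    Y = values.to_numpy(dtype=float).T  # n x genes

    if weights == "voom":
        W = _voom_weights(values, X)
    elif weights == "none":
        W = None
    else:
        raise ValueError(f"unknown weights mode {weights!r}")

    genes = values.index.tolist()
    betas = np.empty(len(genes))
    ts = np.empty(len(genes))
    df = n - X.shape[1]
    if W is None:
        xtx_inv = np.linalg.pinv(X.T @ X)
        H = xtx_inv @ X.T
        coefs = H @ Y  # k x genes
        resid = Y - X @ coefs
        rss = np.sum(resid ** 2, axis=0)
        se_last = np.sqrt(xtx_inv[-1, -1] * rss / df)
        betas = coefs[-1]
        ts = betas / se_last
    else:
        for i in range(len(genes)):
            w = W[i]
            sw = np.sqrt(w)
            Xw = X * sw[:, None]
            yw = Y[:, i] * sw
            xtx_inv = np.linalg.pinv(Xw.T @ Xw)
            coef = xtx_inv @ Xw.T @ yw
            resid = yw - Xw @ coef
            rss = float(resid @ resid)
            se = np.sqrt(xtx_inv[-1, -1] * rss / df)
            betas[i] = coef[-1]
            ts[i] = coef[-1] / se
    ps = 2 * stats.t.sf(np.abs(ts), df)
    qs = bh_fdr(ps)
    return pd.DataFrame({
        "gene": genes,
        "beta": betas,
        "t": ts,
        "p": ps,
        "q": qs,
        "direction": np.sign(betas).astype(int),
    })


def _voom_weights(values: pd.DataFrame, X: np.ndarray) -> np.ndarray:
    """Precision weights from a lowess fit of sqrt residual SD vs mean level."""
    if _lowess is None:  # pragma: no cover
        raise ImportError("statsmodels is required for voom-like weights")
    Y = values.to_numpy(dtype=float).T
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    sd = resid.std(axis=0, ddof=X.shape[1])
    mean_level = values.mean(axis=1).to_numpy()
    trend = _lowess(np.sqrt(sd), mean_level, frac=0.5, return_sorted=False)
    trend = np.clip(trend, 1e-4, None)
    w = 1.0 / trend ** 4  # sqrt-SD trend -> variance = trend^4
    return np.tile(w[:, None], (1, Y.shape[0]))


def fisher_overlap(set_a, set_b, universe) -> tuple[float, float]:
    """Two-sided Fisher's exact test for the overlap of two gene sets.

    The 2x2 table cross-classifies the universe by membership in each set.
    Returns ``(odds_ratio, p)`` where the OR is the sample odds ratio with a
    Haldane 0.5 correction when any cell is zero; p comes from the exact
    hypergeometric enumeration.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a = set(set_a) & universe
    b = set(set_b) & universe
    if set(set_a) - universe or set(set_b) - universe:
        raise ValueError("sets must be subsets of the universe")
    n11 = len(a & b)
    n12 = len(a - b)
    n21 = len(b - a)
    n22 = len(universe) - n11 - n12 - n21
    table = np.array([[n11, n12], [n21, n22]], dtype=float)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if (table == 0).any():
        table = table + 0.5
    odds = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
    return float(odds), float(p)
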