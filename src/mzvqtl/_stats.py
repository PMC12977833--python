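"""Shared regression and multiple-testing primitives.

Small, fast building blocks used across the twin models, the QTL scans and
the interaction tests.  Everything here is ordinary least squares or a
standard FDR procedure; the scientific content lives in the calling modules.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "ols_fit",
    "ols_residuals",
    "corr_pvalues",
    "bh_fdr",
    "storey_qvalue",
]


def ols_fit(X: np.ndarray, y: np.ndarray):
    """OLS fit of ``y`` on design ``X`` (intercept NOT added automatically).

    Returns ``(coef, se, tstat, pvalue, df_resid, residuals)`` where the
    p-values are two-sided from the t distribution with residual degrees of
    freedom.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    df = n - k
    if df < 1:
        raise ValueError(f"degenerate design: n={n} observations, k={k} columns")
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as err:
        raise ValueError("rank-deficient design matrix") from err
    coef = xtx_inv @ (X.T @ y)
    resid = y - X @ coef
    rss = float(resid @ resid)
    sigma2 = rss / df
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, coef / se, 0.0)
    pval = np.where(se > 0, 2.0 * stats.t.sf(np.abs(tstat), df), 1.0)
    return coef, se, tstat, pval, df, resid


def ols_residuals(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residuals of ``y`` regressed on ``X`` via least squares.

    Uses ``lstsq`` so rank-deficient designs (aliased columns) are handled by
    dropping into the minimum-norm solution rather than failing.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def corr_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-values for Pearson correlations ``r`` at sample size ``n``.

    Equivalent to the slope t-test of the simple regression y ~ x, which is
    what a per-SNP QTL scan computes.
    """
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, np.finfo(float).tiny))
    return 2.0 * stats.t.sf(np.abs(t), df)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values with pi0 = 1)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def storey_qvalue(p: np.ndarray, lambdas: np.ndarray | None = None) -> np.ndarray:
    """Storey q-values with the smoother estimate of pi0.

    pi0 is estimated on the grid ``lambdas`` (default 0.05..0.95 step 0.05)
    and smoothed with a cubic polynomial evaluated at the largest lambda,
    then clipped to (0, 1].  With few p-values or a degenerate fit, pi0
    falls back to 1 (the Benjamini-Hochberg limit).
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    if m < 2 * lambdas.size:
        pi0 = 1.0
    else:
        pi0_lam = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
        try:
            coefs = np.polyfit(lambdas, pi0_lam, deg=3)
            pi0 = float(np.polyval(coefs, lambdas.max()))
        except np.linalg.LinAlgError:
            pi0 = float(pi0_lam[-1])
        pi0 = min(max(pi0, 1.0 / m), 1.0)
    return np.minimum(pi0 * bh_fdr(p) / 1.0, 1.0)
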