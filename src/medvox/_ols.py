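"""Closed-form ordinary least squares used throughout the hot paths.

Single fits elsewhere in the scientific Python stack would normally go
through :mod:`statsmodels`; the pipelines here refit the same tiny designs
tens of thousands of times (per voxel, per bootstrap resample, per Monte
Carlo replicate), so the normal equations are solved directly with numpy.
Equivalence with ``statsmodels.OLS`` is asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class SingularFitError(ValueError):
    """Raised when a design matrix is rank deficient."""


@dataclass
class OLSResult:
    params: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    tvalues: np.ndarray
    resid: np.ndarray
    fittedvalues: np.ndarray
    rsquared: float
    df_resid: int
    ssr: float
    xtx_inv: np.ndarray


def add_intercept(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.ndim == 2 and X.shape[1] > 1 and X.shape[0] != X.shape[1]:
        X = X.T
    return np.column_stack([np.ones(X.shape[0]), X])


def ols_fit(y: np.ndarray, X: np.ndarray, names: list[str] | None = None) -> OLSResult:
    """Fit y on a design matrix X (intercept NOT added automatically).

    Raises SingularFitError naming the offending column when the Gram
    matrix is numerically singular.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if n != y.size:
        raise ValueError(f"length mismatch: y has {y.size} rows, X has {n}")
    xtx = X.T @ X
    # detect rank deficiency before solving
    col_sd = X.std(axis=0)
    rank = np.linalg.matrix_rank(xtx)
    if rank < k:
        constant = [i for i, s in enumerate(col_sd[1:], start=1) if s == 0.0]
        if names is None:
            names = [f"x{i}" for i in range(k)]
        offender = (
            ", ".join(names[i] for i in constant)
            if constant
            else "collinear columns " + ", ".join(names[1:])
        )
        raise SingularFitError(f"design is rank deficient (regressor: {offender})")
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ y)
    fitted = X @ beta
    resid = y - fitted
    ssr = float(resid @ resid)
    df_resid = n - k
    sigma2 = ssr / df_resid if df_resid > 0 else np.nan
    bse = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / bse
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ssr / tss if tss > 0 else np.nan
    return OLSResult(beta, bse, pvals, tvals, resid, fitted, r2, df_resid, ssr, xtx_inv)


def slope_pvalue(t: np.ndarray, df: np.ndarray) -> np.ndarray:
    """Two-tailed p-value for a t statistic."""
    return 2.0 * stats.t.sf(np.abs(t), df)


def batched_ols(G: np.ndarray, r: np.ndarray, syy: np.ndarray, n: np.ndarray):
    """Solve many small OLS problems from sufficient statistics.

    Parameters
    ----------
    G : (..., k, k) Gram matrices X'X (intercept included as a column).
    r : (..., k) moment vectors X'y.
    syy : (...,) uncorrected sums of squares y'y.
    n : (...,) sample sizes.

    Returns (beta, se, t, df, ssr, r2) with shapes (..., k) / (...,).
    """
    beta = np.linalg.solve(G, r[..., None])[..., 0]
    Ginv = np.linalg.inv(G)
    ssr = syy - np.einsum("...k,...k->...", beta, r)
    ssr = np.maximum(ssr, 0.0)
    k = G.shape[-1]
    df = n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = ssr / df
        var = sigma2[..., None] * np.einsum("...kk->...k", Ginv)
        se = np.sqrt(np.maximum(var, 0.0))
        t = beta / se
    # total SS about the mean: syy - n * ybar^2; ybar = r[...,0]/n (col 0 = intercept)
    ybar = r[..., 0] / n
    tss = syy - n * ybar**2
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(tss > 0, 1.0 - ssr / tss, np.nan)
    return beta, se, t, df, ssr, r2
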