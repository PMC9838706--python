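"""Regression diagnostics, latent scores, and head-motion controls.

* RESET specification test: powers 2-4 of the (standardized) fitted
  values are added to the design and jointly F-tested (3 numerator df).
* White/Wooldridge heteroscedasticity test: squared residuals are
  regressed on the fitted values and their squares; n R^2 ~ chi^2(2).
* Latent score: first principal component across subtests, sign-aligned
  with the subtest sum, affine-rescaled to a target mean/SD.
* Framewise displacement (FD): per-frame sum of absolute translation
  increments plus a sphere radius times absolute rotation increments;
  summarized as the mean FD and the proportion above a threshold.
* Global residualization: every key variable (age, outcome, moderators,
  each voxel over its available subjects) is replaced by its residual on
  a set of covariates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._ols import SingularFitError, ols_fit
from .simulate import VoxelStack


def reset_test(y, design):
    """RESET: F test of fitted-value powers 2-4 added to the design.

    ``design`` is the regressor matrix without intercept. Returns
    (F, (df1, df2), p).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if n <= k + 1 + 4:
        raise ValueError("too few observations for the RESET test")
    X0 = np.column_stack([np.ones(n), X])
    base = ols_fit(y, X0)
    yhat = base.fittedvalues
    sd = yhat.std()
    if sd == 0:
        raise ValueError("constant fitted values")
    z = (yhat - yhat.mean()) / sd
    Xa = np.column_stack([X0, z**2, z**3, z**4])
    if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
        raise SingularFitError("augmented RESET design is rank deficient")
    aug = ols_fit(y, Xa)
    df1 = 3
    df2 = n - (k + 1) - 3
    F = ((base.ssr - aug.ssr) / df1) / (aug.ssr / df2)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), (df1, df2), p


def white_wooldridge_test(residuals, fitted):
    """Heteroscedasticity: u^2 on (yhat, yhat^2); LM = n R^2 ~ chi^2(2)."""
    u = np.asarray(residuals, dtype=float).ravel()
    f = np.asarray(fitted, dtype=float).ravel()
    if np.ptp(f) == 0:
        raise ValueError("constant fitted values")
    n = u.size
    aux = ols_fit(u**2, np.column_stack([np.ones(n), f, f**2]))
    lm = n * aux.rsquared
    return float(lm), 2, float(stats.chi2.sf(lm, 2))


def diagnostic_report(fit) -> dict:
    """White/Wooldridge heteroscedasticity checks for the three
    mediation regressions, keyed by equation."""
    out = {}
    for eq, resid, fitted in (
        ("eq1", fit.resid_eq1, fit.fitted_eq1),
        ("eq2", fit.resid_eq2, fit.fitted_eq2),
        ("eq3", fit.resid_eq3, fit.fitted_eq3),
    ):
        chi2, df, p = white_wooldridge_test(resid, fitted)
        out[eq] = {"white_chi2": chi2, "white_df": df, "white_p": p}
    return out


def latent_score(subtest_matrix, target_mean: float, target_sd: float):
    """First principal component of standardized subtests, rescaled.

    The sign is chosen so the score correlates positively with the
    subtest sum; the output has exactly the target mean and SD.
    """
    M = np.asarray(subtest_matrix, dtype=float)
    if M.ndim != 2 or M.shape[1] < 2:
        raise ValueError("need at least 2 subtest columns")
    sd = M.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"constant subtest column(s): {bad.tolist()}")
    Zs = (M - M.mean(axis=0)) / sd
    corr = Zs.T @ Zs / (M.shape[0] - 1)
    vals, vecs = np.linalg.eigh(corr)
    v1 = vecs[:, -1]
    score = Zs @ v1
    total = Zs.sum(axis=1)
    if np.corrcoef(score, total)[0, 1] < 0:
        score = -score
    score = (score - score.mean()) / score.std(ddof=1)
    return score * target_sd + target_mean


def fd_summaries(motion_params, radius_mm: float = 50.0, threshold_mm: float = 0.9):
    """Mean framewise displacement and the high-motion proportion.

    ``motion_params`` is (frames, 6): three translations in mm followed
    by three rotations in radians.
    """
    P = np.asarray(motion_params, dtype=float)
    if P.ndim != 2 or P.shape[1] != 6:
        raise ValueError(
            f"motion parameters must have 6 columns (3 translations mm, "
            f"3 rotations rad); got shape {P.shape}"
        )
    if P.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    d = np.abs(np.diff(P, axis=0))
    fd = d[:, :3].sum(axis=1) + radius_mm * d[:, 3:].sum(axis=1)
    return float(fd.mean()), float(np.mean(fd > threshold_mm))


def residualize_all(cohort: pd.DataFrame, stack: VoxelStack, covariate_cols):
    """Regress covariates out of every key variable.

    Age, outcome and moderator columns are replaced by their OLS
    residuals on the covariates (plus intercept); each voxel is
    residualized over its own available subjects. Returns a new cohort
    and stack. Applying the operation twice changes nothing.
    """
    Xc = cohort[list(covariate_cols)].to_numpy(dtype=float)
    n = len(cohort)
    X = np.column_stack([np.ones(n), Xc])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularFitError(f"collinear covariates: {list(covariate_cols)}")

    def resid(y):
        return y - X @ np.linalg.lstsq(X, y, rcond=None)[0]

    out = cohort.copy()
    skip = set(covariate_cols) | {"subject_id"}
    for col in cohort.columns:
        if col in skip or not np.issubdtype(cohort[col].dtype, np.number):
            continue
        out[col] = resid(cohort[col].to_numpy(dtype=float))

    # per-voxel residualization on available subjects only
    V = stack.n_voxels
    vals = stack.values.copy()
    w = stack.mask.astype(float)
    k = X.shape[1]
    G = np.einsum("iv,ik,il->vkl", w, X, X)
    Bm = np.where(stack.mask, vals, 0.0)
    r = np.einsum("ik,iv->vk", X, Bm)
    ok = np.linalg.matrix_rank(G) == k
    beta = np.full((V, k), 0.0)
    beta[ok] = np.linalg.solve(G[ok], r[ok, :, None])[..., 0]
    fitted = np.einsum("ik,vk->iv", X, beta)
    new_vals = np.where(stack.mask, vals - fitted, vals)
    new_stack = VoxelStack(
        new_vals, stack.mask.copy(), stack.coords, stack.ijk, stack.shape,
        stack.affine,
    )
    return out, new_stack
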