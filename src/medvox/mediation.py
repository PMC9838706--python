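"""Single-mediator causal mediation by a system of four linear regressions.

With age A, mediator B and outcome C the system is

    C = i1 + c A            + e1        (total effect)
    C = i2 + b B + c' A     + e2        (direct + mediator effects)
    B = i3 + a A            + e3        (age effect on the mediator)
    C = i4 + b B + c' A + d (A x B) + e4   (moderation-by-age check)

The indirect effect is ab = a * b, identical to c - c' for OLS on the
same sample. Mediation is declared by joint significance: the two-tailed
test of a and a one-tailed test that b has the opposite sign to a, with
the conjunction p-value equal to the maximum of the two. The A x B
product in the fourth equation uses mean-centered A and B, which leaves
the d test and its Cohen's f^2 unchanged while reducing collinearity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._ols import SingularFitError, ols_fit
from .bootstrap import bc_interval


class InsufficientDataError(ValueError):
    pass


@dataclass
class MediationFit:
    a: float
    se_a: float
    p_a: float
    b: float
    se_b: float
    p_b: float
    c: float
    se_c: float
    p_c: float
    c_prime: float
    se_c_prime: float
    p_c_prime: float
    d: float
    se_d: float
    p_d: float
    i1: float
    i2: float
    i3: float
    i4: float
    ab: float
    n: int
    p_b_directional: float
    b_direction_two_tailed: bool
    p_joint: float
    f2_interaction: float
    r2_eq2: float
    r2_eq4: float
    resid_eq1: np.ndarray = field(repr=False)
    resid_eq2: np.ndarray = field(repr=False)
    resid_eq3: np.ndarray = field(repr=False)
    fitted_eq1: np.ndarray = field(repr=False)
    fitted_eq2: np.ndarray = field(repr=False)
    fitted_eq3: np.ndarray = field(repr=False)


def _check_inputs(A, B, C):
    A = np.asarray(A, dtype=float).ravel()
    B = np.asarray(B, dtype=float).ravel()
    C = np.asarray(C, dtype=float).ravel()
    if not (A.size == B.size == C.size):
        raise ValueError("A, B, C must have equal length")
    if A.size < 5:
        raise InsufficientDataError(f"need at least 5 subjects, got {A.size}")
    if np.ptp(A) == 0:
        raise SingularFitError("design is rank deficient (regressor: A)")
    if np.ptp(B) == 0:
        raise SingularFitError("design is rank deficient (regressor: B)")
    return A, B, C


def directional_b_pvalue(b: float, se_b: float, df: int, a_sign: float):
    """One-tailed p that b lies on the side of zero opposite to sign(a).

    Returns (p, two_tailed_fallback): when a is exactly zero there is no
    direction to test against and the two-tailed p is returned, flagged.
    """
    t = b / se_b
    if a_sign == 0:
        return 2.0 * stats.t.sf(abs(t), df), True
    if a_sign > 0:  # consistent mediation needs b < 0
        return float(stats.t.cdf(t, df)), False
    return float(stats.t.sf(t, df)), False


def fit_mediation(A, B, C) -> MediationFit:
    """OLS estimates of the four-equation mediation system."""
    A, B, C = _check_inputs(A, B, C)
    ones = np.ones_like(A)
    eq1 = ols_fit(C, np.column_stack([ones, A]), ["const", "A"])
    eq3 = ols_fit(B, np.column_stack([ones, A]), ["const", "A"])
    eq2 = ols_fit(C, np.column_stack([ones, B, A]), ["const", "B", "A"])
    Ac = A - A.mean()
    Bc = B - B.mean()
    eq4 = ols_fit(
        C, np.column_stack([ones, B, A, Ac * Bc]), ["const", "B", "A", "AxB"]
    )

    a, b = eq3.params[1], eq2.params[1]
    c, c_prime = eq1.params[1], eq2.params[2]
    d = eq4.params[3]
    p_dir, fallback = directional_b_pvalue(b, eq2.bse[1], eq2.df_resid, np.sign(a))
    f2 = _f2(eq4.rsquared, eq2.rsquared)
    return MediationFit(
        a=a, se_a=eq3.bse[1], p_a=eq3.pvalues[1],
        b=b, se_b=eq2.bse[1], p_b=eq2.pvalues[1],
        c=c, se_c=eq1.bse[1], p_c=eq1.pvalues[1],
        c_prime=c_prime, se_c_prime=eq2.bse[2], p_c_prime=eq2.pvalues[2],
        d=d, se_d=eq4.bse[3], p_d=eq4.pvalues[3],
        i1=eq1.params[0], i2=eq2.params[0], i3=eq3.params[0], i4=eq4.params[0],
        ab=a * b, n=A.size,
        p_b_directional=p_dir, b_direction_two_tailed=fallback,
        p_joint=max(eq3.pvalues[1], p_dir),
        f2_interaction=f2,
        r2_eq2=eq2.rsquared, r2_eq4=eq4.rsquared,
        resid_eq1=eq1.resid, resid_eq2=eq2.resid, resid_eq3=eq3.resid,
        fitted_eq1=eq1.fittedvalues, fitted_eq2=eq2.fittedvalues,
        fitted_eq3=eq3.fittedvalues,
    )


def _f2(r2_full: float, r2_reduced: float) -> float:
    if r2_full >= 1.0:
        raise ValueError("degenerate fit: R^2 of the interaction model is 1")
    return max(r2_full - r2_reduced, 0.0) / (1.0 - r2_full)


def moderation_screen(fit: MediationFit, f2_max: float = 0.02, p_min: float = 0.05):
    """Screen for moderation of the direct age effect by the mediator.

    Passes when the interaction is both small (Cohen's f^2 below f2_max)
    and nonsignificant (two-tailed p above p_min, uncorrected).
    Returns (passed, reasons).
    """
    reasons = []
    if not fit.f2_interaction < f2_max:
        reasons.append(f"f2_interaction {fit.f2_interaction:.4f} >= {f2_max}")
    if not fit.p_d > p_min:
        reasons.append(f"p(d) {fit.p_d:.4f} <= {p_min}")
    return len(reasons) == 0, reasons


def _paths_from_indices(A, B, C, idx):
    """Vectorized a, b, c, c' over resamples given an index matrix.

    idx has shape (n_resamples, n); slopes come from the per-resample
    normal equations of the three mediation regressions.
    """
    Ar, Br, Cr = A[idx], B[idx], C[idx]
    n = idx.shape[1]
    mA, mB, mC = Ar.mean(1), Br.mean(1), Cr.mean(1)
    sAA = np.einsum("ij,ij->i", Ar, Ar) / n - mA**2
    sBB = np.einsum("ij,ij->i", Br, Br) / n - mB**2
    sAB = np.einsum("ij,ij->i", Ar, Br) / n - mA * mB
    sAC = np.einsum("ij,ij->i", Ar, Cr) / n - mA * mC
    sBC = np.einsum("ij,ij->i", Br, Cr) / n - mB * mC
    with np.errstate(divide="ignore", invalid="ignore"):
        a = sAB / sAA
        c = sAC / sAA
        det = sBB * sAA - sAB**2
        b = (sBC * sAA - sAB * sAC) / det
        c_prime = (sAC * sBB - sAB * sBC) / det
    return a, b, c, c_prime


def _degenerate_resamples(A: np.ndarray, B: np.ndarray, idx: np.ndarray):
    """Resamples where the mediation system is unidentifiable."""
    Ar, Br = A[idx], B[idx]
    bad = (np.ptp(Ar, axis=1) == 0) | (np.ptp(Br, axis=1) == 0)
    with np.errstate(invalid="ignore"):
        sa = Ar.std(axis=1)
        sb = Br.std(axis=1)
        cov = (Ar * Br).mean(axis=1) - Ar.mean(axis=1) * Br.mean(axis=1)
        r2 = np.where(bad, 1.0, (cov / np.where(bad, 1.0, sa * sb)) ** 2)
    return bad | (r2 >= 1.0 - 1e-12)


@dataclass
class BootstrapAB:
    estimate: float
    ci: tuple[float, float]
    boot: np.ndarray = field(repr=False)
    n_boot: int = 0
    n_redrawn: int = 0
    level: float = 0.95
    components: dict = field(default_factory=dict, repr=False)


def bootstrap_ab(
    A, B, C, n_boot: int = 15_000, seed: int | None = None, level: float = 0.95,
) -> BootstrapAB:
    """BC percentile bootstrap for the indirect effect ab.

    Whole subjects are resampled with replacement and all paths refit per
    resample. Degenerate resamples — constant age or mediator, or B
    exactly collinear with A (rank-deficient direct-effect design) — are
    redrawn and counted; more than 1% redraws triggers a warning.
    """
    A, B, C = _check_inputs(A, B, C)
    if n_boot < 1000:
        raise ValueError("n_boot must be at least 1000")
    rng = np.random.default_rng(seed)
    n = A.size
    point = fit_mediation(A, B, C)
    boots = np.empty(n_boot)
    a_all = np.empty(n_boot)
    b_all = np.empty(n_boot)
    c_all = np.empty(n_boot)
    cp_all = np.empty(n_boot)
    n_redrawn = 0
    filled = 0
    chunk = min(n_boot, 4000)
    while filled < n_boot:
        take = min(chunk, n_boot - filled)
        idx = rng.integers(0, n, size=(take, n))
        bad = _degenerate_resamples(A, B, idx)
        while bad.any():
            n_redrawn += int(bad.sum())
            idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
            bad = _degenerate_resamples(A, B, idx)
        a, b, c, cp = _paths_from_indices(A, B, C, idx)
        sl = slice(filled, filled + take)
        boots[sl] = a * b
        a_all[sl], b_all[sl], c_all[sl], cp_all[sl] = a, b, c, cp
        filled += take
    if n_redrawn > 0.01 * n_boot:
        warnings.warn(
            f"{n_redrawn} degenerate resamples redrawn (> 1% of {n_boot})",
            stacklevel=2,
        )
    ci = bc_interval(boots, point.ab, level)
    return BootstrapAB(
        estimate=point.ab,
        ci=ci,
        boot=boots,
        n_boot=n_boot,
        n_redrawn=n_redrawn,
        level=level,
        components={"a": a_all, "b": b_all, "c": c_all, "c_prime": cp_all},
    )
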