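"""Moderated mediation: a moderator may shift every path of the model.

Following the path-analytic regression framework for moderated
mediation, two stages are fitted with a standardized moderator Z and
mean-centered A and B:

    stage 1:  B = i + a A + a_Z Z + a_AZ (A x Z) + e
    stage 2:  C = i + b B + c' A + b_Z Z + b_BZ (B x Z) + c'_AZ (A x Z) + e

Simple paths are evaluated at Z one SD above and below the mean, e.g.
a(z) = a + a_AZ z, and each Delta is the change across 2 SDs. Single
paths use the parametric t test of the interaction coefficient; compound
paths (the indirect effect ab and the total effect ab + c') use the
bias-corrected percentile bootstrap with whole-subject resampling.

Rows with a missing moderator are dropped listwise (the usable N is
reported), mirroring designs where not every participant answers every
questionnaire item.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._ols import SingularFitError, ols_fit
from .bootstrap import bc_interval, bc_pvalue
from .mediation import InsufficientDataError


@dataclass
class ModMedFit:
    n: int
    n_dropped: int
    # first/second stage coefficients
    a: float
    a_z: float
    a_az: float
    b: float
    c_prime: float
    b_z: float
    b_bz: float
    cp_az: float
    # simple paths at z = -1, +1 SD
    simple: dict
    # deltas across 2 SDs with p-values
    delta_a: float
    p_delta_a: float
    delta_b: float
    p_delta_b: float
    delta_c_prime: float
    p_delta_c_prime: float
    delta_ab: float
    p_delta_ab: float
    delta_total: float
    p_delta_total: float
    ci_delta_ab: tuple
    ci_delta_total: tuple
    boot: dict = field(default_factory=dict, repr=False)


def residualize_moderators(z_target, z_others=None):
    """Residual of one moderator on the others, re-standardized.

    With no other moderators the target is simply standardized.
    Collinear ``z_others`` raise, naming the collinear set.
    """
    z = np.asarray(z_target, dtype=float).ravel()
    if z_others is None or (hasattr(z_others, "size") and z_others.size == 0) or (
        isinstance(z_others, (list, tuple)) and len(z_others) == 0
    ):
        sd = z.std(ddof=1)
        if sd == 0:
            raise ValueError("constant moderator")
        return (z - z.mean()) / sd
    Zo = np.asarray(z_others, dtype=float)
    if Zo.ndim == 1:
        Zo = Zo[:, None]
    X = np.column_stack([np.ones(z.size), Zo])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularFitError(
            f"collinear moderator set ({Zo.shape[1]} columns, rank deficient)"
        )
    resid = z - X @ np.linalg.lstsq(X, z, rcond=None)[0]
    sd = resid.std(ddof=1)
    if sd <= 1e-10 * max(1.0, float(np.abs(z).max())):
        # target lies in the span of the others: constant (zero) residual
        return np.zeros_like(resid)
    return (resid - resid.mean()) / sd


def _stage_designs(A, B, C, Z, include_z: bool = True):
    Ac = A - A.mean()
    Bc = B - B.mean()
    if include_z:
        X1 = np.column_stack([np.ones_like(A), Ac, Z, Ac * Z])
        X2 = np.column_stack([np.ones_like(A), Bc, Ac, Z, Bc * Z, Ac * Z])
    else:
        X1 = np.column_stack([np.ones_like(A), Ac])
        X2 = np.column_stack([np.ones_like(A), Bc, Ac])
    return X1, X2


def _fit_stages(A, B, C, Z, include_z: bool = True):
    X1, X2 = _stage_designs(A, B, C, Z, include_z)
    names1 = ["const", "A", "Z", "AxZ"][: X1.shape[1]]
    names2 = ["const", "B", "A", "Z", "BxZ", "AxZ"][: X2.shape[1]]
    return ols_fit(B, X1, names1), ols_fit(C, X2, names2)


def fit_modmed(A, B, C, Z, n_boot: int = 15_000, seed: int | None = None,
               level: float = 0.95) -> ModMedFit:
    """Fit the moderated mediation model and test path moderation."""
    A = np.asarray(A, dtype=float).ravel()
    B = np.asarray(B, dtype=float).ravel()
    C = np.asarray(C, dtype=float).ravel()
    Z = np.asarray(Z, dtype=float).ravel()
    keep = np.isfinite(A) & np.isfinite(B) & np.isfinite(C) & np.isfinite(Z)
    n_dropped = int((~keep).sum())
    A, B, C, Z = A[keep], B[keep], C[keep], Z[keep]
    n = A.size
    if n < 20:
        raise InsufficientDataError(f"only {n} complete cases")
    sd_z = Z.std(ddof=1)
    if sd_z == 0:
        raise ValueError("constant moderator")
    Z = (Z - Z.mean()) / sd_z

    s1, s2 = _fit_stages(A, B, C, Z)
    a, a_z, a_az = s1.params[1], s1.params[2], s1.params[3]
    b, cp, b_z, b_bz, cp_az = (
        s2.params[1], s2.params[2], s2.params[3], s2.params[4], s2.params[5],
    )

    def simple_at(z):
        av = a + a_az * z
        bv = b + b_bz * z
        cv = cp + cp_az * z
        return {"a": av, "b": bv, "c_prime": cv, "ab": av * bv,
                "total": av * bv + cv}

    simple = {-1.0: simple_at(-1.0), 1.0: simple_at(1.0)}
    delta_a = simple[1.0]["a"] - simple[-1.0]["a"]
    delta_b = simple[1.0]["b"] - simple[-1.0]["b"]
    delta_cp = simple[1.0]["c_prime"] - simple[-1.0]["c_prime"]
    delta_ab = simple[1.0]["ab"] - simple[-1.0]["ab"]
    delta_total = simple[1.0]["total"] - simple[-1.0]["total"]

    boot_ab, boot_total = _bootstrap_deltas(A, B, C, Z, n_boot, seed)
    return ModMedFit(
        n=n, n_dropped=n_dropped,
        a=a, a_z=a_z, a_az=a_az, b=b, c_prime=cp, b_z=b_z, b_bz=b_bz,
        cp_az=cp_az, simple=simple,
        delta_a=delta_a, p_delta_a=s1.pvalues[3],
        delta_b=delta_b, p_delta_b=s2.pvalues[4],
        delta_c_prime=delta_cp, p_delta_c_prime=s2.pvalues[5],
        delta_ab=delta_ab, p_delta_ab=bc_pvalue(boot_ab, delta_ab),
        delta_total=delta_total, p_delta_total=bc_pvalue(boot_total, delta_total),
        ci_delta_ab=bc_interval(boot_ab, delta_ab, level),
        ci_delta_total=bc_interval(boot_total, delta_total, level),
        boot={"delta_ab": boot_ab, "delta_total": boot_total},
    )


def _bootstrap_deltas(A, B, C, Z, n_boot, seed):
    """Vectorized case bootstrap of the compound-path deltas.

    Each resample re-standardizes Z, re-centers A and B, and refits both
    stages by batched normal equations.
    """
    rng = np.random.default_rng(seed)
    n = A.size
    out_ab = np.empty(n_boot)
    out_total = np.empty(n_boot)
    chunk = max(1, min(n_boot, int(4e6) // n))
    done = 0
    while done < n_boot:
        take = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(take, n))
        Ar, Br, Cr, Zr = A[idx], B[idx], C[idx], Z[idx]
        Zr = (Zr - Zr.mean(1, keepdims=True)) / Zr.std(1, ddof=1, keepdims=True)
        Ac = Ar - Ar.mean(1, keepdims=True)
        Bc = Br - Br.mean(1, keepdims=True)
        ones = np.ones_like(Ac)
        X1 = np.stack([ones, Ac, Zr, Ac * Zr], axis=2)
        X2 = np.stack([ones, Bc, Ac, Zr, Bc * Zr, Ac * Zr], axis=2)
        G1 = np.einsum("rik,ril->rkl", X1, X1)
        r1 = np.einsum("rik,ri->rk", X1, Br)
        G2 = np.einsum("rik,ril->rkl", X2, X2)
        r2 = np.einsum("rik,ri->rk", X2, Cr)
        beta1 = np.linalg.solve(G1, r1[..., None])[..., 0]
        beta2 = np.linalg.solve(G2, r2[..., None])[..., 0]
        a, a_az = beta1[:, 1], beta1[:, 3]
        b, cp, b_bz, cp_az = beta2[:, 1], beta2[:, 2], beta2[:, 4], beta2[:, 5]
        ab_hi = (a + a_az) * (b + b_bz)
        ab_lo = (a - a_az) * (b - b_bz)
        d_ab = ab_hi - ab_lo
        d_total = d_ab + 2.0 * cp_az
        out_ab[done : done + take] = d_ab
        out_total[done : done + take] = d_total
        done += take
    return out_ab, out_total
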