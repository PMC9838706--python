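"""Mass-univariate mediation with hierarchical voxel selection.

Per voxel, only subjects with data at that voxel enter the fits. The
selection hierarchy is: (1) Benjamini-Hochberg FDR on the two-tailed
age-path p-values across all voxels passing the availability floor,
defining candidate voxels; (2) exclusion of voxels showing moderation of
the direct age effect (interaction f^2 or p screen); (3) FDR on the
conjunction p (max of the a test and the directional b test) within the
surviving set. Summary voxels additionally require complete data and a
positive mean group contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


from .simulate import VoxelStack


class EmptyResultError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


def fdr_bh(pvalues: np.ndarray, q: float = 0.05):
    """Benjamini-Hochberg step-up. NaN entries are excluded and returned
    unrejected with NaN adjusted p. Returns (reject, p_adjusted)."""
    p = np.asarray(pvalues, dtype=float)
    reject = np.zeros(p.shape, dtype=bool)
    p_adj = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum() == 0:
        return reject, p_adj
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rej, adj, _, _ = multipletests(p[ok], alpha=q, method="fdr_bh")
    reject[ok] = rej
    p_adj[ok] = adj
    return reject, p_adj


@dataclass
class VoxelResultMaps:
    """Per-voxel statistic maps over the stack's voxel set."""

    a: np.ndarray
    se_a: np.ndarray
    p_a: np.ndarray
    b: np.ndarray
    se_b: np.ndarray
    p_b_directional: np.ndarray
    p_joint: np.ndarray
    ab: np.ndarray
    c: np.ndarray
    c_prime: np.ndarray
    d: np.ndarray
    p_d: np.ndarray
    f2_interaction: np.ndarray
    n_available: np.ndarray
    contrast_mean: np.ndarray
    contrast_d: np.ndarray
    p_a_adj: np.ndarray
    p_joint_adj: np.ndarray
    eligible: np.ndarray
    analysis_mask: np.ndarray
    mediation_mask: np.ndarray
    summary_mask: np.ndarray
    stack: VoxelStack = field(repr=False)

    def save_map(self, name: str, path) -> None:
        import nibabel as nib

        arr = getattr(self, name)
        vol = self.stack.to_volume(arr.astype(float), fill=np.nan)
        if arr.dtype == bool:
            vol = np.nan_to_num(vol, nan=0.0).astype(np.uint8)
        nib.save(nib.Nifti1Image(vol, self.stack.affine), str(path))


def _voxel_paths(A: np.ndarray, C: np.ndarray, values: np.ndarray, mask: np.ndarray):
    """Vectorized per-voxel mediation fits under per-voxel missingness.

    Returns a dict of per-voxel arrays; each voxel's statistics use only
    its available subjects.
    """
    w = mask.astype(float)
    n_v = w.sum(axis=0)
    V = values.shape[1]
    Bm = np.where(mask, values, 0.0)

    SA = A @ w
    SAA = (A**2) @ w
    SC = C @ w
    SCC = (C**2) @ w
    SAC = (A * C) @ w
    SB = Bm.sum(axis=0)
    SBB = np.einsum("ij,ij->j", Bm, Bm)
    SAB = A @ Bm
    SBC = C @ Bm

    with np.errstate(divide="ignore", invalid="ignore"):
        mA, mB, mC = SA / n_v, SB / n_v, SC / n_v
        vAA = SAA - SA * mA
        vBB = SBB - SB * mB
        vAB = SAB - SA * mB
        vAC = SAC - SA * mC
        vBC = SBC - SB * mC
        vCC = SCC - SC * mC

        # eq3: B ~ A; eq1: C ~ A
        a = vAB / vAA
        c = vAC / vAA
        ssr3 = vBB - a * vAB
        se_a = np.sqrt(np.maximum(ssr3 / (n_v - 2), 0.0) / vAA)
        t_a = a / se_a
        p_a = 2.0 * stats.t.sf(np.abs(t_a), n_v - 2)

        # eq2: C ~ B + A (centered normal equations per voxel)
        det = vBB * vAA - vAB**2
        b = (vBC * vAA - vAB * vAC) / det
        c_prime = (vAC * vBB - vAB * vBC) / det
        ssr2 = vCC - b * vBC - c_prime * vAC
        sigma2_2 = np.maximum(ssr2 / (n_v - 3), 0.0)
        se_b = np.sqrt(sigma2_2 * vAA / det)
        t_b = b / se_b
        r2_eq2 = np.where(vCC > 0, 1.0 - ssr2 / vCC, np.nan)

    # eq4: C ~ B + A + (A - mA)(B - mB), centered per voxel
    P = (A[:, None] - mA[None, :]) * (values - mB[None, :]) * w
    SP = P.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mP = SP / n_v
        vPP = np.einsum("ij,ij->j", P, P) - SP * mP
        vAP = np.einsum("i,ij->j", A, P) - SA * mP
        vBP = np.einsum("ij,ij->j", Bm, P) - SB * mP
        vCP = np.einsum("i,ij->j", C, P) - SC * mP

        G = np.empty((V, 3, 3))
        G[:, 0, 0], G[:, 0, 1], G[:, 0, 2] = vBB, vAB, vBP
        G[:, 1, 0], G[:, 1, 1], G[:, 1, 2] = vAB, vAA, vAP
        G[:, 2, 0], G[:, 2, 1], G[:, 2, 2] = vBP, vAP, vPP
        r = np.stack([vBC, vAC, vCP], axis=1)
        ok = np.isfinite(G).all(axis=(1, 2)) & (np.linalg.det(G) > 0)
        beta4 = np.full((V, 3), np.nan)
        var_d = np.full(V, np.nan)
        ssr4 = np.full(V, np.nan)
        if ok.any():
            beta4[ok] = np.linalg.solve(G[ok], r[ok, :, None])[..., 0]
            Ginv = np.linalg.inv(G[ok])
            ssr4[ok] = vCC[ok] - np.einsum("ik,ik->i", beta4[ok], r[ok])
            sigma2_4 = np.maximum(ssr4[ok] / (n_v[ok] - 4), 0.0)
            var_d[ok] = sigma2_4 * Ginv[:, 2, 2]
        d = beta4[:, 2]
        se_d = np.sqrt(np.maximum(var_d, 0.0))
        t_d = d / se_d
        p_d = 2.0 * stats.t.sf(np.abs(t_d), n_v - 4)
        r2_eq4 = np.where(vCC > 0, 1.0 - ssr4 / vCC, np.nan)
        f2 = np.maximum(r2_eq4 - r2_eq2, 0.0) / (1.0 - r2_eq4)

        # one-tailed b opposite in sign to a; conjunction p
        cdf_b = stats.t.cdf(t_b, n_v - 3)
        p_b_dir = np.where(a > 0, cdf_b, 1.0 - cdf_b)
        p_b_dir = np.where(a == 0, 2.0 * stats.t.sf(np.abs(t_b), n_v - 3), p_b_dir)
        p_joint = np.maximum(p_a, p_b_dir)

        # one-sample group contrast per voxel
        sd_B = np.sqrt(np.maximum(vBB / (n_v - 1), 0.0))
        contrast_d = mB / sd_B

    return {
        "a": a, "se_a": se_a, "p_a": p_a,
        "b": b, "se_b": se_b, "p_b_directional": p_b_dir, "p_joint": p_joint,
        "ab": a * b, "c": c, "c_prime": c_prime,
        "d": d, "p_d": p_d, "f2_interaction": f2,
        "n_available": n_v.astype(int),
        "contrast_mean": mB, "contrast_d": contrast_d,
    }


def run_voxelwise(
    cohort,
    stack: VoxelStack,
    q: float = 0.05,
    floor: int = 100,
    f2_max: float = 0.02,
    p_min: float = 0.05,
) -> VoxelResultMaps:
    """Per-voxel mediation with the hierarchical selection procedure."""
    A = cohort["A"].to_numpy(dtype=float)
    C = cohort["C"].to_numpy(dtype=float)
    if len(cohort) != stack.n_subjects:
        raise AlignmentError(
            f"cohort has {len(cohort)} subjects, stack has {stack.n_subjects}"
        )
    if floor > stack.n_subjects:
        raise ValueError("floor cannot exceed the number of subjects")
    eligible = stack.available_n >= floor
    if not eligible.any():
        raise EmptyResultError(f"no voxel has at least {floor} available subjects")

    maps = _voxel_paths(A, C, stack.values, stack.mask)
    for key, arr in maps.items():
        if np.issubdtype(arr.dtype, np.floating):
            maps[key] = np.where(eligible, arr, np.nan)

    # stage 1: FDR on the age path over floor-passing voxels
    p_a_stage = np.where(eligible, maps["p_a"], np.nan)
    a_sig, p_a_adj = fdr_bh(p_a_stage, q)

    # stage 2: moderation screen
    screen_pass = (maps["f2_interaction"] < f2_max) & (maps["p_d"] > p_min)
    analysis_mask = eligible & a_sig & screen_pass

    # stage 3: conjunction FDR within the analysis mask
    p_joint_stage = np.where(analysis_mask, maps["p_joint"], np.nan)
    med_sig, p_joint_adj = fdr_bh(p_joint_stage, q)
    mediation_mask = analysis_mask & med_sig

    full_n = maps["n_available"] == stack.n_subjects
    summary_mask = mediation_mask & full_n & (maps["contrast_mean"] > 0)

    return VoxelResultMaps(
        a=maps["a"], se_a=maps["se_a"], p_a=maps["p_a"],
        b=maps["b"], se_b=maps["se_b"],
        p_b_directional=maps["p_b_directional"], p_joint=maps["p_joint"],
        ab=maps["ab"], c=maps["c"], c_prime=maps["c_prime"],
        d=maps["d"], p_d=maps["p_d"], f2_interaction=maps["f2_interaction"],
        n_available=maps["n_available"],
        contrast_mean=maps["contrast_mean"], contrast_d=maps["contrast_d"],
        p_a_adj=p_a_adj, p_joint_adj=p_joint_adj,
        eligible=eligible, analysis_mask=analysis_mask,
        mediation_mask=mediation_mask, summary_mask=summary_mask,
        stack=stack,
    )


def roi_summarize(stack: VoxelStack, roi_masks: dict[str, np.ndarray]):
    """Per-subject mean mediator over available in-ROI voxels.

    Returns a dict name -> series (NaN where a subject has no available
    voxel in the ROI). An empty ROI raises, naming the ROI.
    """
    out = {}
    for name, roi in roi_masks.items():
        roi = np.asarray(roi)
        if roi.shape == stack.shape:
            roi = roi.ravel()
        roi = roi.astype(bool)
        if roi.sum() == 0:
            raise ValueError(f"ROI {name!r} is empty")
        out[name] = stack.summary(roi)
    return out


def summary_mediator(maps: VoxelResultMaps, stack: VoxelStack) -> np.ndarray:
    """Per-subject mean over the summary voxels (significant mediation,
    complete data, positive mean contrast)."""
    if maps.summary_mask.sum() == 0:
        raise EmptyResultError(
            "summary mask is empty: no voxel shows significant mediation with "
            "complete data and a positive mean contrast"
        )
    return stack.summary(maps.summary_mask)
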