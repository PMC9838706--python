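"""Synthetic lifespan cohorts with per-voxel mediator maps.

The generator produces a subject table (age, IQ-like outcome, standardized
lifestyle moderators, head-motion summaries) and a subjects-by-voxels
mediator stack with known ground truth for every downstream stage:

* ages near-uniform over the configured range;
* per-voxel mediator = intercept + (age slope) * age + a shared regional
  error (heavy-tailed by default, so causal direction is identifiable)
  + spatially smoothed voxel noise, renormalized so the configured noise
  SD is the marginal SD after smoothing;
* outcome = intercept + direct age effect + the active region's
  contribution (per-voxel mediator -> outcome slopes averaged over the
  active set) + optional age x mediator interaction + moderator-shifted
  path slopes + a structural error;
* missingness as contiguous edge slabs per subject (bounding-box style),
  with a hard per-voxel floor on the available sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .config import ConfigurationError, SimulationConfig

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

MOTION_COLUMNS = ("motion_mean_fd", "motion_prop_high")


@dataclass
class VoxelStack:
    """Subjects-by-voxels mediator values with availability mask.

    ``values`` and ``mask`` are (n_subjects, n_voxels); ``coords`` are
    world-mm coordinates of each voxel (affine applied to integer grid
    indices); ``ijk`` the integer indices; ``shape`` the 3-D grid shape.
    """

    values: np.ndarray
    mask: np.ndarray
    coords: np.ndarray
    ijk: np.ndarray
    shape: tuple[int, int, int]
    affine: np.ndarray

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    @property
    def available_n(self) -> np.ndarray:
        return self.mask.sum(axis=0)

    def summary(self, voxel_mask: np.ndarray | None = None) -> np.ndarray:
        """Per-subject mean over available voxels (optionally a subset).

        Subjects with no available voxel in the subset get NaN.
        """
        if voxel_mask is None:
            voxel_mask = np.ones(self.n_voxels, dtype=bool)
        voxel_mask = np.asarray(voxel_mask).ravel()
        if voxel_mask.dtype != bool:
            voxel_mask = voxel_mask.astype(bool)
        if voxel_mask.size == self.n_voxels:
            cols = voxel_mask
        else:
            raise ValueError("voxel_mask length does not match stack")
        m = self.mask[:, cols]
        v = np.where(m, self.values[:, cols], 0.0)
        cnt = m.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = v.sum(axis=1) / cnt
        out[cnt == 0] = np.nan
        return out

    def to_volume(self, voxel_values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        vol = np.full(self.shape, fill, dtype=float)
        vol[tuple(self.ijk.T)] = voxel_values
        return vol

    def save_nifti(self, values_path, mask_path) -> None:
        n = self.n_subjects
        vol4 = np.zeros(self.shape + (n,), dtype=np.float32)
        msk4 = np.zeros(self.shape + (n,), dtype=np.uint8)
        idx = tuple(self.ijk.T)
        for i in range(n):
            vol4[idx + (i,)] = self.values[i]
            msk4[idx + (i,)] = self.mask[i]
        nib.save(nib.Nifti1Image(vol4, self.affine), str(values_path))
        nib.save(nib.Nifti1Image(msk4, self.affine), str(mask_path))

    @classmethod
    def load_nifti(cls, values_path, mask_path) -> "VoxelStack":
        vimg = nib.load(str(values_path))
        mimg = nib.load(str(mask_path))
        vol4 = np.asarray(vimg.dataobj, dtype=float)
        msk4 = np.asarray(mimg.dataobj).astype(bool)
        shape = vol4.shape[:3]
        ijk = np.argwhere(np.ones(shape, dtype=bool))
        affine = vimg.affine
        coords = ijk @ affine[:3, :3].T + affine[:3, 3]
        values = vol4.reshape(-1, vol4.shape[3]).T
        mask = msk4.reshape(-1, msk4.shape[3]).T
        return cls(values, mask, coords, ijk, tuple(shape), affine)


def _draw_errors(rng: np.random.Generator, family: str, sd: float, size) -> np.ndarray:
    if family == "gaussian":
        return rng.normal(0.0, sd, size)
    if family == "laplace":
        return rng.laplace(0.0, sd / np.sqrt(2.0), size)
    if family == "uniform":
        return rng.uniform(-sd * np.sqrt(3.0), sd * np.sqrt(3.0), size)
    if family == "exponential-mixture":
        # 3:1 mixture of an exponential and its reflection, centered/scaled
        sign = np.where(rng.random(size) < 0.75, 1.0, -1.0)
        x = sign * rng.exponential(1.0, size)
        return (x - 0.5) * (sd / np.sqrt(1.75))
    raise ConfigurationError(f"unknown error family {family!r}")


def _smoothing_norm(sigma_vox: np.ndarray, shape) -> float:
    """Factor by which smoothing shrinks the marginal SD of white noise.

    Computed from the discrete impulse response of the separable kernel,
    so dividing the smoothed field by this factor restores a unit
    marginal SD away from the grid edges.
    """
    factor = 1.0
    for s, length in zip(sigma_vox, shape):
        if s <= 0:
            continue
        half = max(int(4.0 * s + 0.5), 1)
        if half >= 2 * length:
            raise ConfigurationError(
                f"smoothing kernel (half-width {half} voxels) exceeds grid axis of {length}"
            )
        imp = np.zeros(2 * half + 5)
        imp[half + 2] = 1.0
        k = gaussian_filter1d(imp, s)
        factor *= np.sqrt(float((k**2).sum()))
    return factor


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def _simulate(config: SimulationConfig):
    """Deterministic core: one RNG stream drives cohort and stack."""
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    lo, hi = config.age_range
    A = rng.uniform(lo, hi, n)

    moderators: dict[str, np.ndarray] = {}
    for name, _path, _slope in config.moderator_spec:
        if name not in moderators:
            moderators[name] = _standardize(rng.normal(0.0, 1.0, n))

    # head-motion summaries: mild age dependence, strictly positive
    mean_fd = 0.15 + 0.003 * (A - lo) + np.abs(rng.normal(0.0, 0.05, n))
    prop_high = np.clip(rng.beta(1.2, 30.0, n) + 0.0005 * (A - lo), 0.0, 1.0)

    shape = tuple(config.grid_shape)
    n_vox = int(np.prod(shape))
    sigma_vox = np.array(
        [config.smooth_fwhm * FWHM_TO_SIGMA / vs for vs in config.voxel_size]
    )

    # voxel noise: white -> smoothed -> renormalized to the marginal SD
    eps = rng.standard_normal((n,) + shape)
    if config.smooth_fwhm > 0:
        norm = _smoothing_norm(sigma_vox, shape)
        eps = gaussian_filter(eps, sigma=(0.0, *sigma_vox)) / norm
    eps *= config.noise_sd_mediator

    a_map = config.a_map.ravel()
    active = config.active_mask.ravel()

    theta = {"a": np.zeros(n), "b": np.zeros(n), "c_prime": np.zeros(n)}
    for name, path, slope in config.moderator_spec:
        key = "c_prime" if path in ("c'", "cprime", "c_prime") else path
        theta[key] = theta[key] + slope * moderators[name]

    # regional error shared across the active set (non-Gaussian by default)
    eta = _draw_errors(rng, config.error_family, config.noise_sd_regional, n)

    values = np.empty((n, n_vox))
    values[:] = config.intercept_map.ravel()[None, :]
    values += A[:, None] * a_map[None, :]
    a_active = a_map != 0
    if a_active.any():
        values[:, a_active] += (theta["a"] * A)[:, None]
    if active.any():
        values[:, active] += eta[:, None]
    values += eps.reshape(n, n_vox)

    # outcome from the active region's contribution
    b_map = config.b_map.ravel()
    d_map = config.d_map.ravel()
    C = np.full(n, config.intercept_outcome)
    C += (config.c_prime + theta["c_prime"]) * A
    if active.any():
        contrib = values[:, active] @ b_map[active] / active.sum()
        M = values[:, active].mean(axis=1)
        C += contrib + theta["b"] * (M - M.mean())
    d_active = d_map != 0
    if d_active.any():
        Ac = A - A.mean()
        Bc = values[:, d_active] - values[:, d_active].mean(axis=0)
        C += (Ac[:, None] * Bc) @ d_map[d_active] / d_active.sum()
    C += _draw_errors(rng, config.error_family, config.noise_sd_outcome, n)

    cohort = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "A": A,
            "C": C,
            **moderators,
            "motion_mean_fd": mean_fd,
            "motion_prop_high": prop_high,
        }
    )

    # bounding-box missingness: one face per affected subject, geometric depth
    mask = np.ones((n,) + shape, dtype=bool)
    affected = rng.random(n) < config.missing_prob
    faces = rng.integers(0, 6, n)
    depths = rng.geometric(0.5, n)
    for i in range(n):
        if not affected[i]:
            continue
        axis, side = divmod(int(faces[i]), 2)
        depth = min(int(depths[i]), shape[axis] // 3)
        if depth == 0:
            continue
        sl = [slice(None)] * 3
        sl[axis] = slice(0, depth) if side == 0 else slice(shape[axis] - depth, None)
        mask[(i, *sl)] = False
    mask = mask.reshape(n, n_vox)

    # enforce the per-voxel availability floor by restoring random subjects
    counts = mask.sum(axis=0)
    short = np.flatnonzero(counts < config.missing_floor)
    for v in short:
        missing_rows = np.flatnonzero(~mask[:, v])
        need = config.missing_floor - int(counts[v])
        restore = rng.choice(missing_rows, size=need, replace=False)
        mask[restore, v] = True

    affine = config.affine
    ijk = np.argwhere(np.ones(shape, dtype=bool))
    coords = ijk @ affine[:3, :3].T + affine[:3, 3]
    stack = VoxelStack(values, mask, coords, ijk, shape, affine)

    truth = {
        "ab": float((a_map[active] * b_map[active]).sum() / max(active.sum(), 1)),
        "c_prime": config.c_prime,
        "active_mask": active.copy(),
    }
    truth["total"] = truth["c_prime"] + truth["ab"]
    return cohort, stack, truth


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Subject table: age, outcome, standardized moderators, motion summaries."""
    cohort, _stack, _truth = _simulate(config)
    return cohort


def generate_voxel_stack(config: SimulationConfig, cohort: pd.DataFrame) -> VoxelStack:
    """The voxel stack consistent with a cohort from the same config."""
    own, stack, _truth = _simulate(config)
    if len(own) != len(cohort) or not np.allclose(own["A"], cohort["A"]):
        raise ConfigurationError("cohort does not match this configuration/seed")
    return stack


def simulate_study(config: SimulationConfig):
    """Cohort, stack and the ground-truth summary in one call."""
    return _simulate(config)


def inject_confounder(
    cohort: pd.DataFrame,
    stack: VoxelStack,
    r_um: float,
    r_uy: float,
    seed: int,
    mediator: np.ndarray | None = None,
    given_age: bool = False,
):
    """Construct a latent confounder U with exact sample correlations.

    U is built in the sample space spanned by the mediator summary M and
    the outcome C (plus orthogonalized noise) so that the realized sample
    correlations corr(U, M) and corr(U, C) equal the targets to machine
    precision. With ``given_age=True`` the construction (and hence the
    realized correlations) is in the space of residuals on age, matching
    the age-partialled interpretation used by the sensitivity analysis.
    A target pair incompatible with the existing M-C correlation (the
    implied 3x3 correlation matrix would not be positive semi-definite)
    raises a ValueError.
    """
    if not (abs(r_um) < 1 and abs(r_uy) < 1):
        raise ValueError("target correlations must lie in (-1, 1)")
    rng = np.random.default_rng(seed)
    M = stack.summary() if mediator is None else np.asarray(mediator, dtype=float)
    C = cohort["C"].to_numpy(dtype=float)
    if given_age:
        A = cohort["A"].to_numpy(dtype=float)
        X = np.column_stack([np.ones_like(A), A])
        h = X @ np.linalg.lstsq(X, np.column_stack([M, C]), rcond=None)[0]
        M = M - h[:, 0]
        C = C - h[:, 1]

    def unit(x):
        x = x - x.mean()
        return x / np.linalg.norm(x)

    e1 = unit(M)
    c2 = unit(C)
    rho = float(e1 @ c2)
    if abs(rho) >= 1.0 - 1e-12:
        raise ValueError("mediator and outcome are collinear")
    e2 = unit(c2 - rho * e1)
    # coefficients so corr(U, M) = r_um and corr(U, C) = r_uy exactly
    x = r_um
    y = (r_uy - rho * r_um) / np.sqrt(1.0 - rho**2)
    resid_var = 1.0 - x**2 - y**2
    if resid_var < -1e-12:
        raise ValueError(
            "infeasible confounder targets: the implied correlation matrix of "
            f"(U, M, C) is not positive semi-definite (r_UM={r_um}, r_UY={r_uy}, "
            f"r_MC={rho:.3f})"
        )
    resid_var = max(resid_var, 0.0)
    w = rng.standard_normal(M.size)
    w = w - (w @ e1) * e1 - (w @ e2) * e2
    w = w - w.mean()
    nw = np.linalg.norm(w)
    if nw > 0:
        w = w / nw
    u_unit = x * e1 + y * e2 + np.sqrt(resid_var) * w
    U = u_unit * np.sqrt(M.size)  # unit sample variance (ddof=0)
    return cohort, stack, U


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
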