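"""Simulation configuration for synthetic lifespan cohorts with voxel maps.

The defaults describe the study conditions the package is exercised
under: an adult-lifespan cohort of 252 subjects aged 20.5-90.3 years
(near-uniform by decile), an IQ-like outcome falling 7.2 points per
decade in total (marginal age-outcome correlation near -0.66), about a
fifth of that decline carried through a demand-responsive region whose
per-voxel response declines with age, spatially smoothed voxel noise,
bounding-box missingness with a per-voxel floor of 100 subjects, and
Laplace (heavy-tailed) structural errors so that causal direction is
identifiable from the error distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

ERROR_FAMILIES = ("gaussian", "laplace", "uniform", "exponential-mixture")


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Ground-truth data-generating parameters.

    a_map / b_map / d_map are per-voxel true slopes on the simulation
    grid: age -> mediator (mediator units per year), mediator -> outcome
    (outcome units per mediator unit), and the age x mediator interaction.
    ``c_prime`` is the direct age -> outcome slope (outcome units / year).
    ``moderator_spec`` lists ``(name, path, slope)`` triples: the named
    standardized moderator shifts the given path's slope by ``slope`` per
    SD. ``confounder_spec`` are target correlations of a latent confounder
    with the mediator summary and the outcome.
    """

    n_subjects: int = 252
    age_range: tuple[float, float] = (20.5, 90.3)
    grid_shape: tuple[int, int, int] = (16, 16, 10)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    smooth_fwhm: float = 8.0
    a_map: np.ndarray | None = None
    b_map: np.ndarray | None = None
    d_map: np.ndarray | None = None
    c_prime: float = -0.57
    intercept_mediator: float = 2.1
    intercept_outcome: float = 146.5
    noise_sd_mediator: float = 1.0
    noise_sd_regional: float = 0.4
    noise_sd_outcome: float = 15.0
    error_family: str = "laplace"
    moderator_spec: Sequence[tuple[str, str, float]] = field(
        default_factory=lambda: [
            ("physical", "b", -4.0),
            ("nonphysical", "b", 0.0),
        ]
    )
    confounder_spec: tuple[float, float] = (0.0, 0.0)
    missing_floor: int = 100
    missing_prob: float = 0.5
    seed: int = 0

    # default active region: central block of the grid, optionally with a
    # smooth radial response profile (strong responders respond — and
    # decline — more, coupling contrast strength to mediation strength)
    active_frac: float = 0.4
    a_active: float = -0.016
    b_active: float = 9.375
    d_active: float = 0.0
    taper_profile: bool = True

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ConfigurationError("n_subjects must be >= 4")
        lo, hi = self.age_range
        if not (hi > lo):
            raise ConfigurationError("age_range must be increasing")
        if self.missing_floor > self.n_subjects:
            raise ConfigurationError("missing_floor cannot exceed n_subjects")
        if self.smooth_fwhm < 0:
            raise ConfigurationError("smooth_fwhm must be >= 0")
        for name in ("noise_sd_mediator", "noise_sd_outcome"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.error_family not in ERROR_FAMILIES:
            raise ConfigurationError(
                f"error_family must be one of {ERROR_FAMILIES}, got {self.error_family!r}"
            )
        if any(s < 2 for s in self.grid_shape):
            raise ConfigurationError("each grid axis needs at least 2 voxels")
        if self.a_map is None:
            self.a_map = self._block_map(self.a_active) * self.response_profile
        if self.b_map is None:
            self.b_map = self._block_map(self.b_active)
        if self.d_map is None:
            self.d_map = self._block_map(self.d_active)
        for nm in ("a_map", "b_map", "d_map"):
            arr = np.asarray(getattr(self, nm), dtype=float)
            if arr.shape != tuple(self.grid_shape):
                raise ConfigurationError(f"{nm} shape {arr.shape} != grid {self.grid_shape}")
            setattr(self, nm, arr)

    def _block_map(self, value: float) -> np.ndarray:
        m = np.zeros(self.grid_shape)
        if value != 0.0:
            sl = tuple(
                slice(int(round(s * (1 - self.active_frac) / 2)),
                      int(round(s * (1 + self.active_frac) / 2)))
                for s in self.grid_shape
            )
            m[sl] = value
        return m

    @property
    def active_mask(self) -> np.ndarray:
        """Voxels whose true mediator -> outcome slope is nonzero."""
        return self.b_map != 0

    @property
    def response_profile(self) -> np.ndarray:
        """Unit-mean spatial weight over the active block.

        With ``taper_profile`` the demand response (and the age slope)
        falls off linearly with distance from the block centre, from 1.5x
        to 0.5x the mean; otherwise the block is uniform. The profile is
        1 outside the block.
        """
        block = self._block_map(1.0) != 0
        w = np.ones(self.grid_shape)
        if self.taper_profile and block.any():
            idx = np.argwhere(block).astype(float)
            centre = idx.mean(axis=0)
            d = np.sqrt(((idx - centre) ** 2).sum(axis=1))
            dmax = d.max() if d.max() > 0 else 1.0
            prof = 1.5 - d / dmax
            prof /= prof.mean()
            w[tuple(np.argwhere(block).T)] = prof
        return w

    @property
    def intercept_map(self) -> np.ndarray:
        """Per-voxel demand-response intercept: profiled over the active
        block, zero in non-responsive background."""
        block = self._block_map(1.0) != 0
        return np.where(block, self.intercept_mediator * self.response_profile, 0.0)

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        return aff

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for nm in ("a_map", "b_map", "d_map"):
            d[nm] = np.asarray(d[nm]).tolist()
        d["moderator_spec"] = [list(t) for t in self.moderator_spec]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for nm in ("a_map", "b_map", "d_map"):
            if d.get(nm) is not None:
                d[nm] = np.asarray(d[nm], dtype=float)
        for key in ("age_range", "grid_shape", "voxel_size", "confounder_spec"):
            if key in d:
                d[key] = tuple(d[key])
        if "moderator_spec" in d:
            d["moderator_spec"] = [tuple(t) for t in d["moderator_spec"]]
        return cls(**d)
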