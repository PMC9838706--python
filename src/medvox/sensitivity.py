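"""Left-Out Variables Error (LOVE) sensitivity analysis for mediation.

Asks how strongly an unmodeled confounder U of the mediator-outcome
relation would have to correlate with the mediator (r_UM) and the
outcome (r_UY) to reduce the observed indirect effect to zero. The
adjusted mediator -> outcome slope at a hypothetical (r_UM, r_UY) is the
coefficient B would receive in a regression of C on B and U, computed in
the space of residuals on age by default (age is treated as exogenous):

    b_adj = (r_BC - r_UM r_UY) / (1 - r_UM^2) * (s_C / s_B)

so the adjusted indirect effect ab_adj = a * b_adj vanishes exactly on
the hyperbola r_UM * r_UY = r_BC. Grid points whose implied 3-variable
correlation matrix is not positive semi-definite are flagged infeasible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mediation import MediationFit


@dataclass
class SensitivitySurface:
    grid: np.ndarray  # shared axis for r_UM (rows) and r_UY (columns)
    ab_adj: np.ndarray
    feasible: np.ndarray
    r_bc: float  # (partial) mediator-outcome correlation
    a: float
    ab: float
    scale: float  # s_C / s_B in the residual space
    partial: bool
    contour: np.ndarray = field(repr=False)  # (k, 2) points with ab_adj = 0


def _residual_space(A, B, C, partial: bool):
    A = np.asarray(A, dtype=float).ravel()
    B = np.asarray(B, dtype=float).ravel()
    C = np.asarray(C, dtype=float).ravel()
    if partial:
        X = np.column_stack([np.ones_like(A), A])
        h = X @ np.linalg.lstsq(X, np.column_stack([B, C]), rcond=None)[0]
        Br, Cr = B - h[:, 0], C - h[:, 1]
    else:
        Br, Cr = B - B.mean(), C - C.mean()
    s_b = np.linalg.norm(Br)
    s_c = np.linalg.norm(Cr)
    if s_b == 0 or s_c == 0:
        raise ValueError("degenerate residual space")
    r_bc = float(Br @ Cr / (s_b * s_c))
    return r_bc, s_c / s_b


def adjusted_b(r_um, r_uy, r_bc: float, scale: float):
    """Mediator slope after conditioning on the hypothetical confounder."""
    r_um = np.asarray(r_um, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (r_bc - r_um * np.asarray(r_uy)) / (1.0 - r_um**2) * scale


def love_surface(
    fit: MediationFit,
    A,
    B,
    C,
    grid: np.ndarray | None = None,
    partial: bool = True,
) -> SensitivitySurface:
    """Adjusted indirect effect over a grid of confounder correlations."""
    if grid is None:
        grid = np.linspace(-0.9, 0.9, 101)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.abs(grid) >= 1):
        raise ValueError("grid must lie inside (-1, 1)")
    r_bc, scale = _residual_space(A, B, C, partial)
    RU, RY = np.meshgrid(grid, grid, indexing="ij")
    feasible = 1.0 - RU**2 - RY**2 - r_bc**2 + 2.0 * RU * RY * r_bc >= 0.0
    ab_adj = fit.a * adjusted_b(RU, RY, r_bc, scale)
    ab_adj = np.where(feasible, ab_adj, np.nan)

    # zero contour: sign changes along rows, linear interpolation
    pts = []
    for i, ru in enumerate(grid):
        row = ab_adj[i]
        s = np.sign(row)
        for j in range(len(grid) - 1):
            if np.isnan(row[j]) or np.isnan(row[j + 1]):
                continue
            if s[j] == 0:
                pts.append((ru, grid[j]))
            elif s[j] * s[j + 1] < 0:
                frac = row[j] / (row[j] - row[j + 1])
                pts.append((ru, grid[j] + frac * (grid[j + 1] - grid[j])))
    contour = np.array(pts) if pts else np.empty((0, 2))
    return SensitivitySurface(
        grid=grid, ab_adj=ab_adj, feasible=feasible, r_bc=r_bc,
        a=fit.a, ab=fit.ab, scale=scale, partial=partial, contour=contour,
    )


@dataclass
class ConfoundingThreshold:
    r_star: float  # symmetric threshold on the matched-sign diagonal
    min_single: float  # smallest max-coordinate anywhere on the contour
    min_average: float  # smallest mean-coordinate on the contour
    beyond_grid: bool


def confounding_threshold(surface: SensitivitySurface) -> ConfoundingThreshold:
    """Smallest confounder correlations that nullify the mediation.

    ``r_star`` is the first zero of ab_adj along the diagonal whose sign
    pattern matches the observed mediator-outcome correlation (both
    coordinates of common magnitude r); analytically r* = sqrt(|r_BC|).
    Also reported: the smallest single coordinate that at least one of
    (|r_UM|, |r_UY|) must reach anywhere on the zero contour, and the
    smallest average of the two.
    """
    if surface.ab == 0:
        return ConfoundingThreshold(0.0, 0.0, 0.0, False)
    sign_pair = 1.0 if surface.r_bc >= 0 else -1.0
    rr = surface.grid[surface.grid >= 0]
    vals = surface.a * adjusted_b(rr, sign_pair * rr, surface.r_bc, surface.scale)
    # respect grid feasibility: diagonal of matched sign is always feasible
    s = np.sign(vals)
    r_star = np.nan
    beyond = True
    for j in range(len(rr) - 1):
        if s[j] == 0:
            r_star, beyond = float(rr[j]), False
            break
        if s[j] * s[j + 1] < 0:
            frac = vals[j] / (vals[j] - vals[j + 1])
            r_star = float(rr[j] + frac * (rr[j + 1] - rr[j]))
            beyond = False
            break
    if surface.contour.shape[0]:
        abs_pts = np.abs(surface.contour)
        min_single = float(abs_pts.max(axis=1).min())
        min_average = float(abs_pts.mean(axis=1).min())
    else:
        min_single = min_average = np.nan
    return ConfoundingThreshold(r_star, min_single, min_average, beyond)
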