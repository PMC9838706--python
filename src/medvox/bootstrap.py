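"""Bias-corrected (BC) percentile bootstrap machinery.

One shared implementation backs the indirect-effect intervals, the
moderated-mediation compound-path tests, and the LiNGAM cluster bootstrap.
The interval is the bias-corrected percentile interval without
acceleration: with ``z0 = ndtri(F*(theta_hat))`` estimated from the
fraction of resamples below the point estimate, the (1 - alpha) bounds sit
at the ``ndtr(2 z0 +/- z_{1-alpha/2})`` percentiles of the bootstrap
distribution.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri


def _z0(boot: np.ndarray, estimate: float) -> float:
    b = boot[np.isfinite(boot)]
    if b.size == 0:
        raise ValueError("no finite bootstrap replicates")
    prop = np.mean(b < estimate)
    # clip so z0 stays finite when the estimate falls outside the resample range
    eps = 1.0 / (2.0 * b.size)
    return float(ndtri(np.clip(prop, eps, 1.0 - eps)))


def bc_interval(
    boot: np.ndarray, estimate: float, level: float = 0.95
) -> tuple[float, float]:
    """BC percentile interval for a scalar statistic.

    A perfectly median-unbiased bootstrap distribution (half the resamples
    below the estimate) gives z0 = 0 and the plain percentile interval.
    """
    b = np.asarray(boot, dtype=float)
    b = b[np.isfinite(b)]
    z0 = _z0(b, estimate)
    zq = float(ndtri(0.5 + level / 2.0))
    lo_q = float(ndtr(2.0 * z0 - zq))
    hi_q = float(ndtr(2.0 * z0 + zq))
    return float(np.quantile(b, lo_q)), float(np.quantile(b, hi_q))


def bc_pvalue(boot: np.ndarray, estimate: float, null_value: float = 0.0) -> float:
    """Two-sided p-value by inversion of the BC interval.

    The smallest alpha at which the BC interval excludes ``null_value``.
    """
    b = np.asarray(boot, dtype=float)
    b = b[np.isfinite(b)]
    z0 = _z0(b, estimate)
    eps = 1.0 / (2.0 * b.size)
    p0 = float(np.clip(np.mean(b < null_value), eps, 1.0 - eps))
    z_null = float(ndtri(p0))
    return float(2.0 * ndtr(-abs(z_null - 2.0 * z0)))
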