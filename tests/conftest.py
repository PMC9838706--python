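import numpy as np
import pytest

import medvox as mv


@pytest.fixture(scope="session")
def small_config():
    """Compact study: modest grid, full missingness machinery."""
    return mv.SimulationConfig(
        n_subjects=150,
        grid_shape=(10, 10, 6),
        missing_floor=80,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return mv.simulate_study(small_config)


@pytest.fixture
def mediation_data():
    """Strong, well-conditioned single-mediator dataset."""
    rng = np.random.default_rng(21)
    n = 200
    A = rng.uniform(20, 90, n)
    B = 2.0 - 0.02 * A + rng.standard_normal(n) * 0.5
    C = 100.0 - 5.0 * B - 0.3 * A + rng.standard_normal(n) * 8.0
    return A, B, C


@pytest.fixture
def eight_points():
    """Tiny fixed dataset for normal-equations oracle checks."""
    A = np.array([21.0, 30.0, 38.0, 47.0, 55.0, 64.0, 72.0, 88.0])
    B = np.array([1.9, 1.4, 1.6, 1.1, 1.2, 0.7, 0.9, 0.3])
    C = np.array([118.0, 121.0, 104.0, 97.0, 102.0, 84.0, 91.0, 70.0])
    return A, B, C


def lstsq_oracle(y, X):
    """Independent normal-equations solution: beta, se (no shared code)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    se = np.sqrt(np.diag(xtx_inv) * (resid @ resid) / dof)
    return beta, se
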