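"""Shared fixtures: small synthetic scenes reused across test modules."""

import numpy as np
import pytest

from gwrpm25.synthetic_scene import (
    CONSTANT_BETA,
    constant_coefficient_config,
    simulate,
)


@pytest.fixture(scope="session")
def constant_noiseless_scene():
    """100 stations, one day, constant true coefficients, no noise."""
    cfg = constant_coefficient_config(
        CONSTANT_BETA, n_stations=100, n_days=1, grid_res_km=100.0, noise_sd=0.0, seed=3
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def noisy_scene():
    """150 stations x 2 days with moderate observation noise."""
    cfg = constant_coefficient_config(
        CONSTANT_BETA, n_stations=150, n_days=2, grid_res_km=50.0, noise_sd=6.0, seed=11
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
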