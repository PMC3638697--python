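import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mrewave as mw

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_plane_field(grid, beta, omega, alpha=(0.0, 0.0), amplitude=1.0,
                     anchor=None):
    """Single attenuated plane wave rendered on a grid."""
    if anchor is None:
        anchor = grid.position(grid.nx // 2, grid.ny // 2)
    comp = mw.WaveComponent(amplitude, alpha, beta, anchor)
    return mw.make_wave_field([comp], grid, omega), comp


@pytest.fixture
def grid64():
    return mw.Grid2D(64, 64, 1.0e-3)


@pytest.fixture
def grid128():
    return mw.Grid2D(128, 128, 1.0e-3)


@pytest.fixture(scope="session")
def noisy_replication():
    """One noisy bounded-domain simulation at the default study conditions."""
    res = mw.simulate_experiment(mw.SimulationConfig(seed=1))
    return res
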