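import numpy as np
import pytest

import bnctcam as bc


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def air_config():
    """Spherical source in air, detector at 60 mm."""
    return bc.SimulationConfig(phantom=bc.PhantomGeometry.air(), seed=7)


@pytest.fixture(scope="session")
def small_grid():
    """Desk-size grid for kernel/oracle tests."""
    return bc.VoxelGrid(n_per_axis=24)


@pytest.fixture(scope="session")
def air_events(air_config):
    """A moderate list of true events shared across unit tests."""
    return bc.generate_true_events(air_config, 400)
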