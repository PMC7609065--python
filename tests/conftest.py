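import numpy as np
import pytest

from fretsort import SimulationParams, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_params():
    return SimulationParams()


@pytest.fixture(scope="session")
def small_dataset(default_params):
    """A small balanced dataset reused across tests (session-scoped)."""
    return generate_dataset(400, default_params, seed=99)
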