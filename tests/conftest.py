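import numpy as np
import pytest

from pupilbold import SimulationConfig, simulate_session


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def default_session():
    """One deterministic synthetic session with lag-0 coupling."""
    return simulate_session(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def null_session():
    """A session with no pupil-BOLD coupling."""
    return simulate_session(SimulationConfig(coupling_mode="none", seed=13))
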