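import pytest

from recascan.imaging import FrameGeometry
from recascan.synthetic import SimulationConfig, simulate_sequences


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(rng_seed=1)


@pytest.fixture(scope="session")
def sim_sequences(default_config):
    """One synthetic sequence set with its nine planted domains."""
    return simulate_sequences(default_config)


@pytest.fixture(scope="session")
def frame_geometry():
    return FrameGeometry()
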