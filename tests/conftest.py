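import numpy as np
import pytest

from emgkin import SimulationConfig, generate_session


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Compact session configuration used where full-length sessions would
    only add runtime: 6 repetitions of ~1.6 s with 1.5 s rests (~19 s)."""
    return SimulationConfig(
        seed=3, n_repetitions=6, rep_duration_s=1.6, rest_duration_s=1.5
    )


@pytest.fixture(scope="session")
def small_session(small_config):
    return generate_session(small_config, 1)


@pytest.fixture(scope="session")
def small_pair(small_config):
    return generate_session(small_config, 1), generate_session(small_config, 2)


@pytest.fixture(scope="session")
def default_pair():
    """Default study conditions: two 15-repetition sessions with drift."""
    config = SimulationConfig(seed=11)
    return generate_session(config, 1), generate_session(config, 2)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
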