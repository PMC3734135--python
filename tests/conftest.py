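import numpy as np
import pytest

from voxconn import SimulationConfig, generate_study


@pytest.fixture(scope="session")
def small_config():
    """One subject, one rest + one task session, short run: fast but real."""
    return SimulationConfig(n_subjects=1, n_sessions_per_condition=1,
                            n_volumes=60, seed=42)


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
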