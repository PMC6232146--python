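import numpy as np
import pytest

from grasprsa.protocol import EffectSpec, default_taxonomy, generate_protocol
from grasprsa.searchlight import default_layout
from grasprsa.synth import simulate_session


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy(33)


@pytest.fixture(scope="session")
def small_protocol():
    """4 conditions x 2 repetitions: cheap but structurally complete."""
    return generate_protocol(n_conditions=4, n_repetitions=2, seed=11)


@pytest.fixture(scope="session")
def small_session(small_protocol, layout):
    """One clean synthetic subject at small scale (shared, do not mutate)."""
    effect = EffectSpec(target_channel_nb=5, target_frequency_nb=8,
                        effect_size=1.0, seed=3)
    tax = default_taxonomy(small_protocol.n_conditions)
    return simulate_session(small_protocol, effect, tax, layout, seed=21)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
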