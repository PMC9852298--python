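import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import biproj as bp

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    """The bundled 2-agent, 100-event, 3-type worked-example network."""
    return bp.two_agent_example()


@pytest.fixture(scope="session")
def karate():
    """Ground-truth social graph: 34 nodes, 78 edges."""
    return bp.karate_club_fixture()


@pytest.fixture(scope="session")
def small_sim(karate):
    """One deterministic influence-model realization on the karate graph."""
    from biproj.influence import SimulationConfig, simulate_network

    net, attrs = simulate_network(karate, SimulationConfig(seed=2024))
    return net, attrs


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
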