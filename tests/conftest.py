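import numpy as np
import pytest

from natind import SimulationConfig, Spring, SpringNetwork, generate_random_network


@pytest.fixture
def config():
    return SimulationConfig(seed=0)


@pytest.fixture
def two_mass_net():
    """One plastic spring (k=10, l=10) stretched to separation 15."""
    return SpringNetwork(
        np.array([[0.0, 0.0], [15.0, 0.0]]),
        [Spring(0, 1, 10.0, 10.0, plastic=True)],
    )


@pytest.fixture
def small_net():
    """The small all-plastic system: N=15, 90% connectivity, l0=10, k=10."""
    return generate_random_network(15, 0.9, natural_length=10.0, stiffness=10.0,
                                   plastic=True, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
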