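import numpy as np
import pytest

from fluxbalancer import FluxScenario, branch_network, chain3, coupled_pair, example_network


@pytest.fixture
def pair():
    return coupled_pair()


@pytest.fixture
def pair_scenario():
    return FluxScenario(fixed={"R4": 2.0, "R10": 4.0})


@pytest.fixture
def chain():
    return chain3()


@pytest.fixture
def branch():
    return branch_network()


@pytest.fixture
def example():
    return example_network()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
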