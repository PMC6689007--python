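import numpy as np
import pytest

from scpotency.network import GeneNetwork, network_from_edges
from scpotency.simulate import simulate_network


@pytest.fixture
def path3() -> GeneNetwork:
    return network_from_edges([("a", "b"), ("b", "c")])


@pytest.fixture
def path4() -> GeneNetwork:
    return network_from_edges([("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def triangle() -> GeneNetwork:
    return network_from_edges([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def star3() -> GeneNetwork:
    return network_from_edges([("hub", "x"), ("hub", "y"), ("hub", "z")])


@pytest.fixture
def small_random_net() -> GeneNetwork:
    return simulate_network(n_genes=40, density=0.15, seed=11)


def random_positive_expression(net: GeneNetwork, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.lognormal(0.0, 1.0, size=net.n_nodes)
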