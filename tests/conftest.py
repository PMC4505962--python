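import numpy as np
import pytest

from netmatch.inference import MCMCConfig
from netmatch.netgrow import Graph
from netmatch.synthetic_data import make_stimulus


@pytest.fixture(scope="session")
def stimulus() -> Graph:
    return make_stimulus(seed=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def fast_config() -> MCMCConfig:
    """Reduced MCMC budget for unit tests."""
    return MCMCConfig(n_samples=1500, tune_interval=100, seed=7)


def k4() -> Graph:
    return Graph.from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)])


def path3() -> Graph:
    return Graph.from_edges(3, [(0, 1), (1, 2)])


def star(n: int) -> Graph:
    return Graph.from_edges(n, [(0, i) for i in range(1, n)])


@pytest.fixture
def k4_graph() -> Graph:
    return k4()


@pytest.fixture
def path3_graph() -> Graph:
    return path3()
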