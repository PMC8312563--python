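import numpy as np
import pytest

from wmnet import BinaryNetwork, generate_base_topology


def net_from_edges(n: int, edges) -> BinaryNetwork:
    adj = np.zeros((n, n), dtype=np.int8)
    for a, b in edges:
        adj[a, b] = adj[b, a] = 1
    return BinaryNetwork(adj)


def complete_graph(n: int) -> BinaryNetwork:
    adj = np.ones((n, n), dtype=np.int8) - np.eye(n, dtype=np.int8)
    return BinaryNetwork(adj)


def random_network(n: int, p: float, rng: np.random.Generator) -> BinaryNetwork:
    iu, ju = np.triu_indices(n, 1)
    adj = np.zeros((n, n), dtype=np.int8)
    on = rng.random(iu.size) < p
    adj[iu[on], ju[on]] = 1
    adj[ju[on], iu[on]] = 1
    return BinaryNetwork(adj, validate=False)


@pytest.fixture
def k4() -> BinaryNetwork:
    return complete_graph(4)


@pytest.fixture
def path3() -> BinaryNetwork:
    return net_from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture
def star5() -> BinaryNetwork:
    """Star: center node 0 with 5 leaves."""
    return net_from_edges(6, [(0, i) for i in range(1, 6)])


@pytest.fixture
def cycle6() -> BinaryNetwork:
    return net_from_edges(6, [(i, (i + 1) % 6) for i in range(6)])


@pytest.fixture
def lattice90() -> BinaryNetwork:
    """Ring lattice, 90 nodes, 6 nearest neighbors each."""
    return generate_base_topology(90, 6, rewire_prob=0.0, seed=0)
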