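import numpy as np
import pytest

from ppiscreen import Network


def make_network(edges, disease_id="test", extra_nodes=()):
    return Network.from_edges(disease_id, edges, extra_nodes)


def random_gnp(n, p, seed, disease_id="rand"):
    """Seeded Erdős–Rényi graph over labelled nodes n00..n<n-1>."""
    rng = np.random.default_rng(seed)
    nodes = [f"n{i:02d}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return Network.from_edges(disease_id, edges, extra_nodes=nodes)


@pytest.fixture
def star5():
    """5-node star: center c, leaves l1..l4."""
    return make_network([("c", f"l{i}") for i in range(1, 5)])


@pytest.fixture
def path3():
    return make_network([("A", "B"), ("B", "C")])
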