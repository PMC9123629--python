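import math

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_network, random_gnp
from oracles import brute_force_centralities
from ppiscreen import (
    Network,
    compute_all,
    compute_betweenness,
    compute_closeness,
    compute_degree,
    compute_stress,
)


class TestClosedForms:
    def test_star_center_dominates(self, star5):
        assert compute_degree(star5) == {"c": 4, "l1": 1, "l2": 1,
                                         "l3": 1, "l4": 1}
        bc = compute_betweenness(star5)
        assert bc["c"] == pytest.approx(1.0)
        assert all(bc[f"l{i}"] == 0.0 for i in range(1, 5))
        assert compute_closeness(star5)["c"] == pytest.approx(1.0)
        assert compute_stress(star5)["c"] == 6  # C(4,2) leaf pairs

    def test_path_middle_is_bottleneck(self, path3):
        bc = compute_betweenness(path3)
        assert bc == {"A": 0.0, "B": pytest.approx(1.0), "C": 0.0}
        cc = compute_closeness(path3)
        assert cc["A"] == pytest.approx(2 / 3)
        assert compute_stress(path3)["B"] == 1

    def test_triangle_degrees(self):
        net = make_network([("A", "B"), ("B", "C"), ("C", "A")])
        assert set(compute_degree(net).values()) == {2}

    def test_complete_graph_no_interior_paths(self):
        nodes = list("ABCDE")
        net = make_network([(u, v) for i, u in enumerate(nodes)
                            for v in nodes[i + 1:]])
        assert all(v == 0.0 for v in compute_betweenness(net).values())
        assert all(v == pytest.approx(1.0)
                   for v in compute_closeness(net).values())
        assert all(v == 0 for v in compute_stress(net).values())

    def test_cycle_symmetry(self):
        nodes = [f"v{i}" for i in range(6)]
        net = make_network([(nodes[i], nodes[(i + 1) % 6]) for i in range(6)])
        for metric in (compute_betweenness, compute_closeness, compute_stress):
            values = set(metric(net).values())
            assert len(values) == 1


class TestDegenerateInputs:
    def test_empty_network(self):
        net = Network("x", frozenset(), frozenset())
        assert compute_all(net) == []

    def test_isolated_node_all_zero(self):
        net = make_network([("A", "B")], extra_nodes=["Z"])
        rec = {r.node: r for r in compute_all(net)}["Z"]
        assert (rec.degree, rec.betweenness, rec.closeness, rec.stress) \
            == (0, 0.0, 0.0, 0)

    def test_small_graph_betweenness_defined_zero(self):
        net = make_network([("A", "B")])
        assert compute_betweenness(net) == {"A": 0.0, "B": 0.0}

    def test_disconnected_graph_values_finite_and_in_range(self):
        net = make_network([("A", "B"), ("B", "C"), ("X", "Y")])
        for r in compute_all(net):
            assert 0.0 <= r.betweenness <= 1.0
            assert 0.0 <= r.closeness <= 1.0
            assert r.stress >= 0 and r.degree >= 0
            assert math.isfinite(r.betweenness) and math.isfinite(r.closeness)


@pytest.mark.parametrize("seed", range(8))
def test_matches_enumeration_oracle_on_random_graphs(seed):
    """Brandes-style accumulation equals explicit path enumeration."""
    net = random_gnp(12, 0.3, seed)
    oracle = brute_force_centralities(sorted(net.nodes), net.edges)
    assert compute_degree(net) == oracle["degree"]
    assert compute_stress(net) == oracle["stress"]
    bc, cc = compute_betweenness(net), compute_closeness(net)
    for v in net.nodes:
        assert bc[v] == pytest.approx(oracle["betweenness"][v], abs=1e-9)
        assert cc[v] == pytest.approx(oracle["closeness"][v], abs=1e-9)


@pytest.mark.parametrize("seed,p", [(0, 0.2), (1, 0.4), (2, 0.7)])
def test_cross_check_against_networkx(seed, p):
    """Independent library cross-check for BC and CC conventions."""
    net = random_gnp(18, p, seed)
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from(net.edges)
    nx_bc = nx.betweenness_centrality(g, normalized=True)
    nx_cc = nx.closeness_centrality(g, wf_improved=False)
    bc, cc = compute_betweenness(net), compute_closeness(net)
    for v in net.nodes:
        assert bc[v] == pytest.approx(nx_bc[v], abs=1e-9)
        assert cc[v] == pytest.approx(nx_cc[v], abs=1e-9)


@given(
    edges=st.lists(
        st.tuples(st.integers(0, 9), st.integers(0, 9)).map(
            lambda t: (f"n{t[0]}", f"n{t[1]}")
        ),
        max_size=20,
    ),
    extra=st.tuples(st.integers(0, 9), st.integers(0, 9)).map(
        lambda t: (f"n{t[0]}", f"n{t[1]}")
    ),
)
@settings(deadline=None, max_examples=80, derandomize=True)
def test_handshake_and_degree_monotonicity(edges, extra):
    net = make_network(edges)
    deg = compute_degree(net)
    assert sum(deg.values()) == 2 * net.n_edges
    if extra[0] != extra[1]:
        bigger = make_network(list(edges) + [extra])
        deg2 = compute_degree(bigger)
        assert all(deg2[v] >= deg[v] for v in net.nodes)


def test_compute_all_consistent_with_single_metrics():
    from ppiscreen import ScenarioConfig, generate_network

    net = generate_network(ScenarioConfig(seed=5), 0)
    records = {r.node: r for r in compute_all(net)}
    deg, bc = compute_degree(net), compute_betweenness(net)
    cc, stress = compute_closeness(net), compute_stress(net)
    for v in net.nodes:
        r = records[v]
        assert (r.degree, r.stress) == (deg[v], stress[v])
        assert r.betweenness == bc[v] and r.closeness == cc[v]


def test_compute_all_ordering_degree_desc_then_label():
    net = make_network([("B", "C"), ("A", "C"), ("A", "B"), ("C", "D")])
    names = [r.node for r in compute_all(net)]
    assert names == ["C", "A", "B", "D"]
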