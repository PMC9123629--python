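"""Node centralities for undirected, unweighted interaction networks.

Four topological indices are computed per node, matching the conventions of
classical interactome analysis tools:

degree (K)
    number of distinct direct neighbours.
betweenness centrality (BC)
    fraction of shortest paths between other node pairs passing through the
    node, counted once per unordered pair and normalised by
    ``2 / ((n-1)(n-2))`` with ``n`` the total node count of the graph (not
    the component size).  Unreachable pairs contribute nothing; for n < 3
    all values are 0.
closeness centrality (CC)
    (number of nodes reachable from v) / (sum of hop distances to them).
    Restricting to the reachable set keeps the index defined on disconnected
    graphs; an isolated node scores 0.
stress
    raw integer count of shortest paths (over unordered pairs of *other*
    nodes) that contain the node as an interior vertex.

All computations use a single-source Brandes-style accumulation, O(n·m)
overall, over breadth-first shortest-path DAGs.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Sequence

from .netio import Network


@dataclass(frozen=True)
class CentralityRecord:
    """The four centrality values of one node."""

    node: str
    degree: int
    betweenness: float
    closeness: float
    stress: int


def _bfs_dag(adj: dict[str, set[str]], s: str):
    """BFS from ``s``: returns (visit order, predecessors, path counts, dists)."""
    dist = {s: 0}
    sigma = {s: 1}
    pred: dict[str, list[str]] = {s: []}
    order: list[str] = []
    queue = deque([s])
    while queue:
        v = queue.popleft()
        order.append(v)
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                sigma[w] = 0
                pred[w] = []
                queue.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
                pred[w].append(v)
    return order, pred, sigma, dist


def compute_degree(net: Network) -> dict[str, int]:
    """Number of distinct neighbours per node."""
    return {v: len(nb) for v, nb in net.adjacency().items()}


def compute_betweenness(net: Network) -> dict[str, float]:
    """Normalised betweenness centrality per node (values in [0, 1])."""
    adj = net.adjacency()
    n = len(adj)
    bc = {v: 0.0 for v in adj}
    if n < 3:
        return bc
    for s in adj:
        order, pred, sigma, _ = _bfs_dag(adj, s)
        delta = {v: 0.0 for v in order}
        for w in reversed(order):
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    # each unordered pair was accumulated from both endpoints: halve, then
    # normalise by the number of ordered other-node pairs (n-1)(n-2)/... the
    # combined factor is 1 / ((n-1)(n-2)).
    scale = 1.0 / ((n - 1) * (n - 2))
    return {v: bc[v] * scale for v in bc}


def compute_closeness(net: Network) -> dict[str, float]:
    """Reachable-set closeness centrality per node (values in [0, 1])."""
    adj = net.adjacency()
    cc = {}
    for s in adj:
        _, _, _, dist = _bfs_dag(adj, s)
        total = sum(dist.values())  # dist[s] = 0 contributes nothing
        reachable = len(dist) - 1
        cc[s] = reachable / total if total > 0 else 0.0
    return cc


def compute_stress(net: Network) -> dict[str, int]:
    """Raw shortest-path stress per node.

    For each source the number of shortest paths from the source through a
    node ``v`` to any farther target equals ``sigma[v] * T[v]``, where
    ``T[v]`` counts shortest-path continuations from ``v`` in the BFS DAG;
    summing over sources double-counts each unordered pair.
    """
    adj = net.adjacency()
    acc = {v: 0 for v in adj}
    for s in adj:
        order, pred, sigma, _ = _bfs_dag(adj, s)
        t = {v: 0 for v in order}
        for w in reversed(order):
            for v in pred[w]:
                t[v] += 1 + t[w]
        for v in order:
            if v != s:
                acc[v] += sigma[v] * t[v]
    return {v: acc[v] // 2 for v in acc}


def compute_all(net: Network) -> list[CentralityRecord]:
    """All four centralities per node, ordered by (degree desc, label asc)."""
    adj = net.adjacency()
    if not adj:
        return []
    deg = compute_degree(net)
    bc = compute_betweenness(net)
    cc = compute_closeness(net)
    stress = compute_stress(net)
    records = [
        CentralityRecord(v, deg[v], bc[v], cc[v], stress[v]) for v in adj
    ]
    records.sort(key=lambda r: (-r.degree, r.node))
    return records


def degree_map(records: Sequence[CentralityRecord]) -> dict[str, int]:
    """Convenience: node → degree from a record list."""
    return {r.node: r.degree for r in records}
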