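"""Brute-force centrality oracles, independent of the library implementation.

All-pairs shortest paths are enumerated explicitly (recursive expansion of
BFS predecessor DAGs), and betweenness / stress / closeness are computed by
literally counting paths.  Exponential in the worst case — use on small
graphs only.
"""

from collections import deque


def adjacency(nodes, edges):
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def bfs_distances(adj, s):
    dist = {s: 0}
    queue = deque([s])
    while queue:
        v = queue.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                queue.append(w)
    return dist


def all_shortest_paths(adj, s, t):
    """Every shortest s→t path as an explicit node list."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []

    def extend(path):
        v = path[-1]
        if v == t:
            yield list(path)
            return
        for w in adj[v]:
            if w in dist and dist[w] == dist[v] + 1 and dist[w] <= dist[t]:
                yield from extend(path + [w])

    return list(extend([s]))


def brute_force_centralities(nodes, edges):
    """degree / betweenness / closeness / stress maps by explicit counting."""
    nodes = list(nodes)
    adj = adjacency(nodes, edges)
    n = len(nodes)
    degree = {v: len(adj[v]) for v in nodes}
    bc_raw = {v: 0.0 for v in nodes}
    stress = {v: 0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            paths = all_shortest_paths(adj, s, t)
            if not paths:
                continue
            sigma = len(paths)
            interior = {}
            for path in paths:
                for v in path[1:-1]:
                    interior[v] = interior.get(v, 0) + 1
            for v, cnt in interior.items():
                bc_raw[v] += cnt / sigma
                stress[v] += cnt
    if n >= 3:
        scale = 2.0 / ((n - 1) * (n - 2))
        betweenness = {v: bc_raw[v] * scale for v in nodes}
    else:
        betweenness = {v: 0.0 for v in nodes}
    closeness = {}
    for v in nodes:
        dist = bfs_distances(adj, v)
        total = sum(dist.values())
        closeness[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return {
        "degree": degree,
        "betweenness": betweenness,
        "closeness": closeness,
        "stress": stress,
    }
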