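"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-implementations — path enumeration, matrix
power series, exhaustive draw counting — kept free of the package's own code
paths (and of the library routines the package delegates to) so they can
serve as ground truth on small inputs.
"""

from __future__ import annotations

import itertools

import numpy as np


def _adj(graph) -> dict:
    return {v: set(graph[v]) for v in graph}


def _all_simple_paths(adj, s, t, max_len):
    """DFS enumeration of simple paths from s to t up to max_len edges."""
    stack = [(s, [s])]
    while stack:
        v, path = stack.pop()
        if v == t:
            yield path
            continue
        if len(path) > max_len:
            continue
        for u in adj[v]:
            if u not in path:
                stack.append((u, path + [u]))


def brute_betweenness(graph, normalized=True) -> dict:
    """Betweenness by enumerating every simple path between every pair."""
    adj = _adj(graph)
    nodes = list(graph)
    n = len(nodes)
    bc = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = list(_all_simple_paths(adj, s, t, n))
        if not paths:
            continue
        d = min(len(p) for p in paths)
        geodesics = [p for p in paths if len(p) == d]
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in geodesics if v in p)
            bc[v] += through / len(geodesics)
    if normalized and n > 2:
        scale = (n - 1) * (n - 2) / 2
        bc = {v: x / scale for v, x in bc.items()}
    return bc


def _bfs_distances(adj, source) -> dict:
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for v in frontier:
            for u in adj[v]:
                if u not in dist:
                    dist[u] = dist[v] + 1
                    nxt.append(u)
        frontier = nxt
    return dist


def brute_closeness(graph) -> dict:
    """Component-restricted closeness with the (|C|-1)/(n-1) correction."""
    adj = _adj(graph)
    n = len(adj)
    out = {}
    for v in adj:
        dist = _bfs_distances(adj, v)
        reach = len(dist) - 1
        total = sum(dist.values())
        if reach == 0 or n == 1:
            out[v] = 0.0
        else:
            out[v] = (reach / total) * (reach / (n - 1))
    return out


def brute_degree(graph) -> dict:
    return {v: len(set(graph[v])) for v in graph}


def brute_neighborhood_connectivity(graph) -> dict:
    adj = _adj(graph)
    return {
        v: (sum(len(adj[u]) for u in adj[v]) / len(adj[v]) if adj[v] else 0.0)
        for v in adj
    }


def brute_lac(graph) -> dict:
    adj = _adj(graph)
    out = {}
    for v in adj:
        nbrs = adj[v]
        if not nbrs:
            out[v] = 0.0
            continue
        induced = sum(1 for a, b in itertools.combinations(sorted(nbrs), 2) if b in adj[a])
        out[v] = 2.0 * induced / len(nbrs)
    return out


def series_subgraph_centrality(graph, terms: int = 60) -> dict:
    """SC via the truncated closed-walk series sum_{l<=terms} (A^l)_vv / l!."""
    nodes = sorted(graph)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for v in nodes:
        for u in graph[v]:
            a[idx[v], idx[u]] = 1.0
    acc = np.eye(n)  # l = 0 term
    term = np.eye(n)
    for l in range(1, terms + 1):
        term = term @ a / l
        acc += term
    return {v: float(acc[idx[v], idx[v]]) for v in nodes}


def enumerate_hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by counting every size-n draw from an N-item population."""
    population = [1] * K + [0] * (N - K)
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(population[i] for i in draw) >= k:
            hits += 1
    return hits / total


def enumerate_hypergeom_all_tails(K: int, n: int, N: int) -> dict[int, float]:
    """Tail probabilities for every k at once (single enumeration pass)."""
    population = [1] * K + [0] * (N - K)
    counts = [0] * (n + 1)
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        counts[sum(population[i] for i in draw)] += 1
    tails = {}
    acc = 0
    for k in range(n, -1, -1):
        acc += counts[k]
        tails[k] = acc / total
    return tails


def random_graphs(n_graphs: int, max_n: int, seed: int, min_n: int = 2, p_range=(0.1, 0.9)):
    """Seeded stream of small labeled random graphs as adjacency-dict networkx graphs."""
    import networkx as nx

    rng = np.random.default_rng(seed)
    for _ in range(n_graphs):
        n = int(rng.integers(min_n, max_n + 1))
        p = float(rng.uniform(*p_range))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31 - 1)))
        yield nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
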