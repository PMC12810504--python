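"""Independent brute-force oracles used to validate the graph and
statistics engines.  These deliberately avoid the library calls the
implementation uses: distances come from a hand-rolled BFS, betweenness
from explicit enumeration of every shortest path, and the hypergeometric
tail from exact binomial-coefficient arithmetic.
"""
from __future__ import annotations

import itertools
from collections import deque
from math import comb


def bfs_distances(adj: dict, source) -> dict:
    """Hand-rolled BFS shortest-path distances from ``source``."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def all_shortest_paths(adj: dict, s, t) -> list[list]:
    """Every shortest s-t path, by DFS over the BFS distance layers."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        for v in adj[u]:
            if dist.get(v) == dist[u] + 1 and dist[v] <= dist[t]:
                path.append(v)
                extend(path)
                path.pop()

    extend([s])
    return [p for p in paths if len(p) - 1 == dist[t]]


def brute_betweenness(adj: dict, normalized: bool = True) -> dict:
    """Betweenness by explicit enumeration of all shortest paths,
    endpoints excluded, normalized by (n-1)(n-2)/2."""
    nodes = sorted(adj)
    n = len(nodes)
    bet = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bet[v] += through / len(paths)
    if normalized and n > 2:
        scale = 2.0 / ((n - 1) * (n - 2))
        bet = {v: b * scale for v, b in bet.items()}
    return bet


def brute_closeness(adj: dict) -> dict:
    """Closeness as reciprocal mean BFS distance to reachable nodes."""
    out = {}
    for v in adj:
        dist = bfs_distances(adj, v)
        del dist[v]
        out[v] = len(dist) / sum(dist.values()) if dist else 0.0
    return out


def brute_path_length(adj: dict) -> float:
    """Mean BFS distance over connected ordered pairs."""
    total, pairs = 0, 0
    for v in adj:
        dist = bfs_distances(adj, v)
        del dist[v]
        total += sum(dist.values())
        pairs += len(dist)
    return total / pairs if pairs else 0.0


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """Exact P[X >= k] for X ~ Hypergeometric(N, K, n) from binomial
    coefficients."""
    denom = comb(N, n)
    total = sum(comb(K, j) * comb(N - K, n - j)
                for j in range(k, min(K, n) + 1))
    return total / denom


def hypergeom_by_enumeration(k: int, universe: list, term: set,
                             n: int) -> float:
    """P[|draw ∩ term| >= k] by enumerating every size-n draw (tiny N)."""
    hits = 0
    total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(term & set(draw)) >= k:
            hits += 1
    return hits / total


def k_core_members(adj: dict, k: int) -> set:
    """Nodes of the k-core, by repeatedly deleting degree-<k nodes."""
    adj = {v: set(ns) for v, ns in adj.items()}
    remaining = set(adj)
    while True:
        prune = {v for v in remaining if len(adj[v] & remaining) < k}
        if not prune:
            return remaining
        remaining -= prune


def brute_core_numbers(adj: dict) -> dict:
    """Core number per node by independent pruning at every k."""
    core = {v: 0 for v in adj}
    k = 1
    while True:
        members = k_core_members(adj, k)
        if not members:
            return core
        for v in members:
            core[v] = k
        k += 1
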