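"""Brute-force reference implementations, independent of the package.

Deliberately naive: triangle enumeration, per-pair BFS, exhaustive
shortest-path enumeration, literal step-up FDR.  Only usable for tiny
inputs; the test suite checks the package against these.
"""
from __future__ import annotations

from collections import deque
from itertools import combinations

import numpy as np


def brute_clustering(adj) -> np.ndarray:
    adj = np.asarray(adj)
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(1 for a, b in combinations(nbrs, 2) if adj[a, b])
        out[i] = 2.0 * links / (k * (k - 1))
    return out


def _bfs_dist(adj, s) -> np.ndarray:
    n = adj.shape[0]
    dist = np.full(n, np.inf)
    dist[s] = 0
    q = deque([s])
    while q:
        u = q.popleft()
        for v in np.flatnonzero(adj[u]):
            if dist[v] == np.inf:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def brute_path_length_connected_pairs(adj) -> float:
    adj = np.asarray(adj)
    n = adj.shape[0]
    ds = []
    for s in range(n):
        dist = _bfs_dist(adj, s)
        for t in range(s + 1, n):
            if np.isfinite(dist[t]):
                ds.append(dist[t])
    if not ds:
        raise ValueError("no connected pairs")
    return float(np.mean(ds))


def _all_shortest_paths(adj, s, t):
    """Every geodesic from s to t, found by layered DFS."""
    dist = _bfs_dist(adj, s)
    if not np.isfinite(dist[t]):
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        for v in np.flatnonzero(adj[u]):
            if dist[v] == dist[u] + 1 and dist[t] >= dist[v]:
                path.append(v)
                extend(path)
                path.pop()

    extend([s])
    return paths


def brute_betweenness(adj) -> np.ndarray:
    """Raw fractional betweenness by enumerating every shortest path."""
    adj = np.asarray(adj)
    n = adj.shape[0]
    out = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = _all_shortest_paths(adj, s, t)
            if not paths:
                continue
            for path in paths:
                for v in path[1:-1]:
                    out[v] += 1.0 / len(paths)
    return out


def brute_lcc(adj, removed=()) -> int:
    """Largest connected component size after deleting ``removed`` nodes."""
    adj = np.asarray(adj)
    n = adj.shape[0]
    alive = [v for v in range(n) if v not in set(removed)]
    if not alive:
        return 0
    seen = set()
    best = 0
    alive_set = set(alive)
    for start in alive:
        if start in seen:
            continue
        comp = {start}
        q = deque([start])
        while q:
            u = q.popleft()
            for v in np.flatnonzero(adj[u]):
                if v in alive_set and v not in comp:
                    comp.add(v)
                    q.append(v)
        seen |= comp
        best = max(best, len(comp))
    return best


def bh_step_up(p_values, q) -> np.ndarray:
    """Literal Benjamini-Hochberg: largest k with p_(k) <= k q / m."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    flags = np.zeros(m, dtype=bool)
    for rank in range(k_star):
        flags[order[rank]] = True
    return flags


def random_graph(rng, n=None, p=None):
    """Erdos-Renyi adjacency matrix with a numpy Generator."""
    if n is None:
        n = int(rng.integers(2, 9))
    if p is None:
        p = float(rng.uniform(0.15, 0.9))
    a = (rng.random((n, n)) < p).astype(np.uint8)
    a = np.triu(a, 1)
    return a + a.T
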