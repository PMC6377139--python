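"""Resilience of binary networks to random failure and targeted attack.

The outcome measure is the relative size of the largest connected component
(LCC) as nodes are deleted one at a time.  Single-trajectory curves are
computed with a reverse union-find pass (add nodes back in reverse removal
order), which is O(E alpha(N)) and fast enough to sit inside permutation
loops.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import ValidationError, as_rng, trapezoid_auc
from .metrics import betweenness_centrality, _adj

__all__ = [
    "AttackSchedule",
    "ResilienceCurve",
    "lcc_trajectory",
    "targeted_attack_curve",
    "random_failure_curve",
    "resilience_auc",
    "attack_auc_from_edges",
]


@dataclass(frozen=True)
class AttackSchedule:
    """How nodes are removed.

    ``kind`` is ``random`` or ``targeted_betweenness``; ``ranking_mode``
    selects whether betweenness is ranked once on the intact graph
    (``static``, default) or re-ranked after every removal (``recomputed``).
    """

    kind: str = "targeted_betweenness"
    ranking_mode: str = "static"
    n_random_sequences: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("random", "targeted_betweenness"):
            raise ValidationError(f"unknown attack kind {self.kind!r}")
        if self.ranking_mode not in ("static", "recomputed"):
            raise ValidationError(f"unknown ranking_mode {self.ranking_mode!r}")
        if self.n_random_sequences < 1:
            raise ValidationError("n_random_sequences must be >= 1")


@dataclass(frozen=True)
class ResilienceCurve:
    """Relative LCC size after removing 0, 1, ..., N-1 nodes."""

    fraction_removed: np.ndarray
    relative_lcc: np.ndarray
    auc: float
    kind: str = ""


class _UnionFind:
    __slots__ = ("parent", "size")

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.size = [1] * n

    def find(self, x: int) -> int:
        p = self.parent
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:
            p[x], x = root, p[x]
        return root

    def union(self, a: int, b: int) -> int:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return self.size[ra]
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]
        return self.size[ra]


def lcc_trajectory(n: int, edges_i: np.ndarray, edges_j: np.ndarray,
                   order: np.ndarray) -> np.ndarray:
    """Relative LCC sizes along one removal sequence.

    ``order`` lists all ``n`` node indices in removal order.  Entry ``k`` of
    the result is LCC(graph after removing the first ``k`` nodes) / n, for
    k = 0 .. n-1.  Computed by replaying the removals backwards with
    union-find.
    """
    order = np.asarray(order)
    if order.shape != (n,) or np.bincount(order, minlength=n).max() != 1:
        raise ValidationError("order must be a permutation of all nodes")
    pos = np.empty(n, dtype=np.int64)
    pos[order] = np.arange(n)
    # edge becomes live (in the reverse process) once its later-removed
    # endpoint has been added back, i.e. at reverse time n-1-min(pos_u, pos_v)
    t_live = n - 1 - np.minimum(pos[edges_i], pos[edges_j])
    by_time = np.argsort(t_live, kind="stable")
    ei = edges_i[by_time].tolist()
    ej = edges_j[by_time].tolist()
    bounds = np.searchsorted(t_live[by_time], np.arange(n + 1)).tolist()
    uf = _UnionFind(n)
    union = uf.union
    best = 1 if n else 0
    sizes = [0] * n  # sizes[t] = LCC with t+1 nodes present
    for t in range(n):
        for e in range(bounds[t], bounds[t + 1]):
            s = union(ei[e], ej[e])
            if s > best:
                best = s
        sizes[t] = best
    return np.asarray(sizes[::-1], dtype=float) / n


def _edges(net):
    a = _adj(net)
    n = a.shape[0]
    i, j = np.triu_indices(n, k=1)
    keep = a[i, j] > 0
    return n, i[keep], j[keep]


def targeted_attack_curve(net, schedule: AttackSchedule | None = None) -> ResilienceCurve:
    """Remove nodes in decreasing betweenness order, tracking the relative LCC.

    Static mode ranks once on the intact network (ties broken by node
    index); recomputed mode re-ranks on the surviving subgraph after every
    removal.
    """
    schedule = schedule or AttackSchedule(kind="targeted_betweenness")
    if schedule.kind != "targeted_betweenness":
        raise ValidationError("schedule.kind must be targeted_betweenness")
    n, ei, ej = _edges(net)
    fractions = np.arange(n) / n
    if schedule.ranking_mode == "static":
        b = betweenness_centrality(net)
        order = np.lexsort((np.arange(n), -b))
        values = lcc_trajectory(n, ei, ej, order)
    else:
        values = _recomputed_attack(_adj(net))
    return ResilienceCurve(fractions, values, trapezoid_auc(values, fractions),
                           kind="targeted_betweenness")


def _recomputed_attack(a: np.ndarray) -> np.ndarray:
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    n = a.shape[0]
    alive = np.ones(n, dtype=bool)
    values = np.empty(n)
    work = a.copy()
    for k in range(n):
        idx = np.flatnonzero(alive)
        sub = work[np.ix_(idx, idx)]
        if len(idx) == 0:
            break
        _, labels = connected_components(sp.csr_matrix(sub), directed=False)
        values[k] = np.bincount(labels).max() / n
        b = betweenness_centrality(sub)
        victim = idx[np.lexsort((idx, -b))[0]]
        alive[victim] = False
    return values


def random_failure_curve(net, schedule: AttackSchedule | None = None) -> ResilienceCurve:
    """Mean relative-LCC trajectory over independent random removal orders."""
    schedule = schedule or AttackSchedule(kind="random")
    if schedule.kind != "random":
        raise ValidationError("schedule.kind must be random")
    n, ei, ej = _edges(net)
    rng = as_rng(schedule.seed)
    acc = np.zeros(n)
    for _ in range(schedule.n_random_sequences):
        acc += lcc_trajectory(n, ei, ej, rng.permutation(n))
    values = acc / schedule.n_random_sequences
    fractions = np.arange(n) / n
    return ResilienceCurve(fractions, values, trapezoid_auc(values, fractions),
                           kind="random")


def resilience_auc(curve: ResilienceCurve) -> float:
    """Trapezoidal integral of the relative LCC over the removed fraction."""
    if len(curve.fraction_removed) < 2:
        raise ValidationError("resilience AUC needs a curve with >= 2 points")
    return trapezoid_auc(curve.relative_lcc, curve.fraction_removed)


# ---------------------------------------------------------------------------
# fast array-level entry points for permutation loops
# ---------------------------------------------------------------------------

def attack_auc_from_edges(n: int, ei: np.ndarray, ej: np.ndarray) -> float:
    """Static betweenness-targeted attack AUC for an edge-list graph."""
    import igraph as ig

    g = ig.Graph(n=n, edges=list(zip(ei.tolist(), ej.tolist())))
    b = np.asarray(g.betweenness(), dtype=float)
    order = np.lexsort((np.arange(n), -b))
    values = lcc_trajectory(n, ei, ej, order)
    return trapezoid_auc(values, np.arange(n) / n)


def random_failure_auc_from_edges(n: int, ei: np.ndarray, ej: np.ndarray,
                                  n_sequences: int, rng) -> float:
    """Mean random-failure attack AUC for an edge-list graph."""
    rng = as_rng(rng)
    acc = np.zeros(n)
    for _ in range(n_sequences):
        acc += lcc_trajectory(n, ei, ej, rng.permutation(n))
    values = acc / n_sequences
    return trapezoid_auc(values, np.arange(n) / n)
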