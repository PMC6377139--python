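"""Global and nodal graph metrics with degree-preserving normalization.

Clustering is computed from the adjacency matrix directly, path lengths via
scipy's C-level BFS, and betweenness via igraph's Brandes implementation;
all three are cross-checked against brute-force oracles in the test suite.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path

from ._util import ValidationError, as_rng, trapezoid_auc
from .network import BinaryNetwork

__all__ = [
    "NodalMetrics",
    "GlobalMetrics",
    "MetricCurve",
    "RandomEnsemble",
    "clustering_coefficients",
    "characteristic_path_length",
    "betweenness_centrality",
    "nodal_metrics",
    "degree_preserving_randomize",
    "random_ensemble",
    "normalized_metrics",
    "metric_curve",
]


def _adj(net) -> np.ndarray:
    a = net.adjacency if isinstance(net, BinaryNetwork) else np.asarray(net)
    return a.astype(np.uint8)


@dataclass(frozen=True)
class NodalMetrics:
    clustering: np.ndarray
    betweenness: np.ndarray
    degree: np.ndarray


@dataclass(frozen=True)
class GlobalMetrics:
    """Raw metrics plus random-reference means and their ratios.

    ``gamma``/``sigma`` are ``None`` (missing, never infinity) when the
    reference clustering mean is zero.
    """

    C: float
    L: float
    C_rand: float | None = None
    L_rand: float | None = None
    gamma: float | None = None
    lambda_: float | None = None
    sigma: float | None = None


@dataclass(frozen=True)
class MetricCurve:
    metric_name: str
    densities: np.ndarray
    values: np.ndarray
    auc: float

    def __post_init__(self):
        if len(self.densities) != len(self.values):
            raise ValidationError("densities and values must have equal length")


@dataclass(frozen=True)
class RandomEnsemble:
    source: BinaryNetwork
    n_random: int
    seed: int
    members: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# nodal / global metrics
# ---------------------------------------------------------------------------

def clustering_coefficients(net) -> tuple[np.ndarray, float]:
    """Per-node triangle density among neighbours, and its mean.

    C_i = 2 t_i / (k_i (k_i - 1)) with t_i the triangle count at node i;
    nodes of degree < 2 get C_i = 0.
    """
    a = _adj(net).astype(float)
    k = a.sum(axis=1)
    t = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * t / np.where(denom > 0, denom, 1.0), 0.0)
    return c, float(c.mean())


def characteristic_path_length(net, disconnected_policy: str = "connected_pairs") -> float:
    """Mean shortest-path length between node pairs.

    ``connected_pairs`` averages over reachable pairs only; ``harmonic``
    returns 1 / global efficiency with unreachable pairs contributing zero
    efficiency.
    """
    a = _adj(net)
    n = a.shape[0]
    if n < 2 or a.sum() == 0:
        raise ValidationError("path length needs >= 2 nodes and >= 1 edge")
    dist = shortest_path(sp.csr_matrix(a), method="D", unweighted=True, directed=False)
    iu = np.triu_indices(n, k=1)
    d = dist[iu]
    if disconnected_policy == "connected_pairs":
        finite = d[np.isfinite(d)]
        return float(finite.mean())
    if disconnected_policy == "harmonic":
        with np.errstate(divide="ignore"):
            eff = np.where(np.isfinite(d), 1.0 / d, 0.0).mean()
        if eff == 0:
            raise ValidationError("zero global efficiency")
        return float(1.0 / eff)
    raise ValidationError(f"unknown disconnected_policy {disconnected_policy!r}")


def betweenness_centrality(net) -> np.ndarray:
    """Raw (unnormalized) betweenness with fractional shortest-path counting."""
    a = _adj(net)
    n = a.shape[0]
    i, j = np.triu_indices(n, k=1)
    keep = a[i, j] > 0
    g = ig.Graph(n=n, edges=list(zip(i[keep].tolist(), j[keep].tolist())))
    return np.asarray(g.betweenness(), dtype=float)


def nodal_metrics(net) -> NodalMetrics:
    a = _adj(net)
    c, _ = clustering_coefficients(a)
    return NodalMetrics(clustering=c, betweenness=betweenness_centrality(a),
                        degree=a.sum(axis=1).astype(int))


# ---------------------------------------------------------------------------
# degree-preserving null model
# ---------------------------------------------------------------------------

def degree_preserving_randomize(net, n_swaps_factor: float = 10, seed=0) -> BinaryNetwork:
    """Double-edge-swap rewiring with ``n_swaps_factor * |E|`` attempted swaps.

    Swaps that would create a self-loop or duplicate edge are rejected, so
    the degree sequence is preserved exactly.  Graphs with < 2 edges (or no
    legal swap, e.g. K3) come back unchanged.
    """
    a = _adj(net)
    names = net.roi_names if isinstance(net, BinaryNetwork) else None
    n = a.shape[0]
    i, j = np.triu_indices(n, k=1)
    keep = a[i, j] > 0
    edges = list(zip(i[keep].tolist(), j[keep].tolist()))
    n_edges = len(edges)
    if n_edges >= 2:
        rng = as_rng(seed)
        edge_set = set(edges)
        attempts = int(n_swaps_factor * n_edges)
        pick = rng.integers(0, n_edges, size=(attempts, 2))
        flip = rng.random(attempts) < 0.5
        for t in range(attempts):
            e1, e2 = pick[t]
            if e1 == e2:
                continue
            u, v = edges[e1]
            x, y = edges[e2]
            if flip[t]:
                x, y = y, x
            # propose (u, x) and (v, y)
            if u == x or v == y:
                continue
            new1 = (u, x) if u < x else (x, u)
            new2 = (v, y) if v < y else (y, v)
            if new1 in edge_set or new2 in edge_set:
                continue
            edge_set.discard(edges[e1])
            edge_set.discard(edges[e2])
            edge_set.add(new1)
            edge_set.add(new2)
            edges[e1] = new1
            edges[e2] = new2
    out = np.zeros_like(a)
    if edges:
        ei, ej = zip(*edges)
        out[list(ei), list(ej)] = 1
        out |= out.T
    dr = net.density_requested if isinstance(net, BinaryNetwork) else 0.5
    da = net.density_actual if isinstance(net, BinaryNetwork) else 0.5
    return BinaryNetwork(out, dr, da, list(names) if names else [])


def random_ensemble(net, n_random: int = 20, seed: int = 0,
                    n_swaps_factor: float = 10) -> RandomEnsemble:
    """Ensemble of degree-matched rewired references, one substream per member."""
    if n_random < 1:
        raise ValidationError("n_random must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_random)
    members = [degree_preserving_randomize(net, n_swaps_factor, np.random.default_rng(c))
               for c in children]
    return RandomEnsemble(source=net, n_random=n_random, seed=seed, members=members)


def normalized_metrics(net, ensemble: RandomEnsemble,
                       disconnected_policy: str = "connected_pairs") -> GlobalMetrics:
    """C, L and their ratios to the rewired-ensemble means."""
    if not ensemble.members:
        raise ValidationError("ensemble is empty")
    _, c = clustering_coefficients(net)
    length = characteristic_path_length(net, disconnected_policy)
    c_rand = float(np.mean([clustering_coefficients(m)[1] for m in ensemble.members]))
    l_rand = float(np.mean([characteristic_path_length(m, disconnected_policy)
                            for m in ensemble.members]))
    gamma = c / c_rand if c_rand > 0 else None
    lambda_ = length / l_rand if l_rand > 0 else None
    sigma = gamma / lambda_ if gamma is not None and lambda_ else None
    return GlobalMetrics(C=c, L=length, C_rand=c_rand, L_rand=l_rand,
                         gamma=gamma, lambda_=lambda_, sigma=sigma)


# ---------------------------------------------------------------------------
# density curves
# ---------------------------------------------------------------------------

def _curve_value(net, name, disconnected_policy, ensemble_kwargs):
    if name == "clustering":
        return clustering_coefficients(net)[1]
    if name == "path_length":
        return characteristic_path_length(net, disconnected_policy)
    if name == "degree_sum":
        return float(_adj(net).sum())
    if name in ("gamma", "lambda", "sigma"):
        ens = random_ensemble(net, **ensemble_kwargs)
        gm = normalized_metrics(net, ens, disconnected_policy)
        val = {"gamma": gm.gamma, "lambda": gm.lambda_, "sigma": gm.sigma}[name]
        return np.nan if val is None else val
    raise ValidationError(f"unknown metric {name!r}")


def metric_curve(networks, metric_name, disconnected_policy: str = "connected_pairs",
                 func=None, n_random: int = 20, seed: int = 0) -> MetricCurve:
    """Evaluate a metric over a density sweep and summarise it by trapezoid AUC.

    ``func(net) -> float`` overrides the built-in metric registry; a
    single-density sweep yields a zero-width integral (AUC 0).
    """
    if not networks:
        raise ValidationError("empty density sweep")
    densities = np.array([n.density_requested for n in networks], dtype=float)
    kw = {"n_random": n_random, "seed": seed}
    if func is not None:
        values = np.array([func(n) for n in networks], dtype=float)
    else:
        values = np.array([_curve_value(n, metric_name, disconnected_policy, kw)
                           for n in networks], dtype=float)
    return MetricCurve(metric_name, densities, values,
                       trapezoid_auc(values, densities))
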