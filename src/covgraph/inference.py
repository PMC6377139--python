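"""Permutation-based group comparison of AUC statistics, with FDR control.

The observed statistic is always ``control minus patient`` on the AUC scale.
The null sample comes from relabeling subjects while preserving the two
group sizes; one shared set of relabelings is used across densities and
ROIs within a run.  p-values use the add-one Monte-Carlo convention,
p = (#{null >= observed} + 1) / (n_permutations + 1), so they are never 0.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import scipy.sparse as sp
from scipy import stats
from scipy.sparse.csgraph import shortest_path

from ._util import ValidationError, as_rng, round_half_up, trapezoid_auc
from .cohort import ROIVolumeTable
from .network import DensityGrid, ranked_positive_edges
from .resilience import lcc_trajectory

__all__ = [
    "PermutationConfig",
    "GroupComparisonResult",
    "RegionalResult",
    "permute_group_labels",
    "compare_global_metric",
    "compare_regional_clustering",
    "compare_resilience",
    "bh_fdr",
    "t_test_from_summary",
    "pearson_chi2_2x2",
]


@dataclass(frozen=True)
class PermutationConfig:
    """Settings for the relabeling test.

    ``direction`` applies to one-tailed tests only: ``control_gt_patient``
    rejects for large observed control-minus-patient differences,
    ``patient_gt_control`` for small (negative) ones.
    """

    n_permutations: int = 1000
    tails: str = "one"
    seed: int = 0
    statistic: str = "auc_difference"
    direction: str = "control_gt_patient"

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.tails not in ("one", "two"):
            raise ValidationError("tails must be 'one' or 'two'")
        if self.statistic not in ("auc_difference", "per_density_difference"):
            raise ValidationError(f"unknown statistic {self.statistic!r}")
        if self.direction not in ("control_gt_patient", "patient_gt_control"):
            raise ValidationError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class GroupComparisonResult:
    metric_name: str
    observed: float
    null_sample: np.ndarray
    p_value: float
    per_density_p: np.ndarray | None = None
    n_permutations: int = 0
    tails: str = "one"
    direction: str = "control_gt_patient"
    seed: int = 0
    n_redraws: int = 0
    control_curve: np.ndarray | None = None
    patient_curve: np.ndarray | None = None
    densities: np.ndarray | None = None


@dataclass(frozen=True)
class RegionalResult:
    roi_names: list[str]
    observed_diffs: np.ndarray
    p_values: np.ndarray
    fdr_significant: np.ndarray
    q: float = 0.05
    n_permutations: int = 0
    tails: str = "one"
    direction: str = "control_gt_patient"
    seed: int = 0


# ---------------------------------------------------------------------------
# relabeling
# ---------------------------------------------------------------------------

def permute_group_labels(table: ROIVolumeTable, seed) -> ROIVolumeTable:
    """Uniformly random relabeling preserving both group sizes."""
    labels = table.group_labels()
    names = list(dict.fromkeys(labels))
    if len(names) != 2:
        raise ValidationError("table must contain exactly two groups")
    rng = as_rng(seed)
    return table.with_group_labels(labels[rng.permutation(len(labels))])


# ---------------------------------------------------------------------------
# per-group curve statistics on raw arrays (permutation-loop hot path)
# ---------------------------------------------------------------------------

class _DegenerateGroup(Exception):
    """A relabeled group produced a constant ROI column."""


def _corr(x: np.ndarray) -> np.ndarray:
    if x.shape[0] < 3:
        raise ValidationError("need >= 3 subjects per group")
    if np.any(x.std(axis=0) == 0):
        raise _DegenerateGroup
    return np.corrcoef(x, rowvar=False)


def _sweep_edges(r: np.ndarray, densities: np.ndarray):
    """Yield (m, ii, jj) per density from one descending edge ranking."""
    n = r.shape[0]
    ii, jj, n_pos = ranked_positive_edges(r)
    total = n * (n - 1) // 2
    for d in densities:
        m = min(round_half_up(float(d) * total), n_pos)
        yield m, ii[:m], jj[:m]


def _clustering_from_edges(n, ei, ej) -> np.ndarray:
    a = np.zeros((n, n))
    a[ei, ej] = 1.0
    a += a.T
    k = a.sum(axis=1)
    t = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = k * (k - 1)
    return np.where(denom > 0, 2.0 * t / np.where(denom > 0, denom, 1.0), 0.0)


def _stat_clustering(x, densities, _rng):
    r = _corr(x)
    n = r.shape[0]
    return np.array([_clustering_from_edges(n, ei, ej).mean()
                     for _, ei, ej in _sweep_edges(r, densities)])


def _stat_path_length(x, densities, _rng, policy="connected_pairs"):
    r = _corr(x)
    n = r.shape[0]
    iu = np.triu_indices(n, k=1)
    out = np.empty(len(densities))
    for q, (m, ei, ej) in enumerate(_sweep_edges(r, densities)):
        a = np.zeros((n, n), dtype=np.uint8)
        a[ei, ej] = 1
        a |= a.T
        if m == 0:
            out[q] = np.nan
            continue
        dist = shortest_path(sp.csr_matrix(a), method="D", unweighted=True,
                             directed=False)[iu]
        if policy == "harmonic":
            with np.errstate(divide="ignore"):
                eff = np.where(np.isfinite(dist), 1.0 / dist, 0.0).mean()
            out[q] = 1.0 / eff if eff > 0 else np.nan
        else:
            out[q] = dist[np.isfinite(dist)].mean()
    return out


def _stat_targeted_attack(x, densities, _rng):
    r = _corr(x)
    n = r.shape[0]
    fractions = np.arange(n) / n
    out = np.empty(len(densities))
    for q, (m, ei, ej) in enumerate(_sweep_edges(r, densities)):
        g = ig.Graph(n=n, edges=list(zip(ei.tolist(), ej.tolist())))
        b = np.asarray(g.betweenness(), dtype=float)
        order = np.lexsort((np.arange(n), -b))
        out[q] = trapezoid_auc(lcc_trajectory(n, ei, ej, order), fractions)
    return out


def _make_stat_random_attack(n_sequences: int):
    def _stat(x, densities, rng):
        r = _corr(x)
        n = r.shape[0]
        fractions = np.arange(n) / n
        out = np.empty(len(densities))
        orders = [rng.permutation(n) for _ in range(n_sequences)]
        for q, (m, ei, ej) in enumerate(_sweep_edges(r, densities)):
            acc = np.zeros(n)
            for order in orders:
                acc += lcc_trajectory(n, ei, ej, order)
            out[q] = trapezoid_auc(acc / n_sequences, fractions)
        return out
    return _stat


def _stat_nodal_clustering(x, densities, _rng):
    """Per-ROI nodal clustering, one row per density."""
    r = _corr(x)
    n = r.shape[0]
    return np.stack([_clustering_from_edges(n, ei, ej)
                     for _, ei, ej in _sweep_edges(r, densities)])


_GLOBAL_STATS = {
    "clustering": _stat_clustering,
    "path_length": _stat_path_length,
}


# ---------------------------------------------------------------------------
# permutation engine
# ---------------------------------------------------------------------------

_MAX_REDRAWS = 200


def _run_permutations(x, is_control, densities, stat_fn, config):
    """Observed and null AUC-difference statistics under relabeling.

    Returns (observed_diff, control_curve, patient_curve, null, null_curves,
    n_redraws); ``null_curves`` holds the per-density difference for each
    permutation. Degenerate relabelings (constant column) are redrawn.
    """
    rng = as_rng(config.seed)
    n_c = int(is_control.sum())
    n_subj = x.shape[0]

    def curves(mask):
        return stat_fn(x[mask], densities, rng), stat_fn(x[~mask], densities, rng)

    ctrl, pat = curves(is_control)
    observed_curve = ctrl - pat
    observed = trapezoid_auc(ctrl, densities) - trapezoid_auc(pat, densities)
    null = np.empty(config.n_permutations)
    null_curves = np.empty((config.n_permutations, len(densities)))
    redraws = 0
    for b in range(config.n_permutations):
        while True:
            mask = np.zeros(n_subj, dtype=bool)
            mask[rng.permutation(n_subj)[:n_c]] = True
            try:
                c, p = curves(mask)
                break
            except _DegenerateGroup:
                redraws += 1
                if redraws > _MAX_REDRAWS:
                    raise ValidationError("too many degenerate relabelings")
        null_curves[b] = c - p
        null[b] = trapezoid_auc(c, densities) - trapezoid_auc(p, densities)
    return observed, ctrl, pat, null, null_curves, redraws


def _p_value(null: np.ndarray, observed: float, tails: str, direction: str) -> float:
    n = len(null)
    if tails == "two":
        count = int(np.sum(np.abs(null) >= np.abs(observed)))
    elif direction == "control_gt_patient":
        count = int(np.sum(null >= observed))
    else:
        count = int(np.sum(null <= observed))
    return (count + 1) / (n + 1)


def _split_masks(table: ROIVolumeTable):
    labels = table.group_labels()
    names = list(dict.fromkeys(labels))
    if len(names) != 2:
        raise ValidationError("table must contain exactly two groups")
    if "control" in names:
        control = "control"
    else:
        control = names[0]
    return np.asarray(labels) == control


def compare_global_metric(table: ROIVolumeTable, metric_name: str,
                          grid: DensityGrid, config: PermutationConfig,
                          disconnected_policy: str = "connected_pairs"
                          ) -> GroupComparisonResult:
    """Permutation test of the between-group AUC difference of a global metric.

    ``metric_name`` is ``clustering`` or ``path_length``; resilience metrics
    have their own entry point (:func:`compare_resilience`).
    """
    if metric_name not in _GLOBAL_STATS:
        raise ValidationError(f"unknown global metric {metric_name!r}")
    if metric_name == "path_length":
        def stat_fn(x, d, r):
            return _stat_path_length(x, d, r, policy=disconnected_policy)
    else:
        stat_fn = _GLOBAL_STATS[metric_name]
    return _compare(table, metric_name, grid, config, stat_fn)


def compare_resilience(table: ROIVolumeTable, grid: DensityGrid,
                       attack_kind: str, config: PermutationConfig,
                       n_random_sequences: int = 50) -> GroupComparisonResult:
    """Permutation test of attack-resilience AUC.

    Per density the attack curve's AUC is computed; those values form each
    group's density curve, and the compared statistic is that curve's AUC
    difference (control minus patient).
    """
    if attack_kind == "targeted_betweenness":
        stat_fn = _stat_targeted_attack
    elif attack_kind == "random":
        stat_fn = _make_stat_random_attack(n_random_sequences)
    else:
        raise ValidationError(f"unknown attack kind {attack_kind!r}")
    return _compare(table, f"resilience_{attack_kind}", grid, config, stat_fn)


def _compare(table, name, grid, config, stat_fn) -> GroupComparisonResult:
    x = table.volumes()
    is_control = _split_masks(table)
    if is_control.sum() < 3 or (~is_control).sum() < 3:
        raise ValidationError("both groups need >= 3 subjects")
    densities = grid.values
    observed, ctrl, pat, null, null_curves, redraws = _run_permutations(
        x, is_control, densities, stat_fn, config)
    per_density_p = None
    if config.statistic == "per_density_difference":
        obs_curve = ctrl - pat
        per_density_p = np.array([
            _p_value(null_curves[:, q], obs_curve[q], config.tails, config.direction)
            for q in range(len(densities))])
    return GroupComparisonResult(
        metric_name=name, observed=observed, null_sample=null,
        p_value=_p_value(null, observed, config.tails, config.direction),
        per_density_p=per_density_p, n_permutations=config.n_permutations,
        tails=config.tails, direction=config.direction, seed=config.seed,
        n_redraws=redraws, control_curve=ctrl, patient_curve=pat,
        densities=densities)


def compare_regional_clustering(table: ROIVolumeTable, grid: DensityGrid,
                                config: PermutationConfig, q: float = 0.05
                                ) -> RegionalResult:
    """Per-ROI permutation test of nodal-clustering AUC, BH-corrected.

    One shared set of relabelings serves all ROIs, consistent with
    permuting whole subjects.
    """
    if table.n_rois < 2:
        raise ValidationError("regional clustering needs >= 2 ROIs")
    x = table.volumes()
    is_control = _split_masks(table)
    if is_control.sum() < 3 or (~is_control).sum() < 3:
        raise ValidationError("both groups need >= 3 subjects")
    densities = grid.values
    rng = as_rng(config.seed)
    n_subj, n_rois = x.shape
    n_c = int(is_control.sum())

    def roi_aucs(mask):
        c = _stat_nodal_clustering(x[mask], densities, rng)   # densities x rois
        p = _stat_nodal_clustering(x[~mask], densities, rng)
        diff = c - p
        return np.array([trapezoid_auc(diff[:, k], densities) for k in range(n_rois)])

    observed = roi_aucs(is_control)
    null = np.empty((config.n_permutations, n_rois))
    redraws = 0
    for b in range(config.n_permutations):
        while True:
            mask = np.zeros(n_subj, dtype=bool)
            mask[rng.permutation(n_subj)[:n_c]] = True
            try:
                null[b] = roi_aucs(mask)
                break
            except _DegenerateGroup:
                redraws += 1
                if redraws > _MAX_REDRAWS:
                    raise ValidationError("too many degenerate relabelings")
    p_values = np.array([
        _p_value(null[:, k], observed[k], config.tails, config.direction)
        for k in range(n_rois)])
    return RegionalResult(
        roi_names=list(table.roi_names), observed_diffs=observed,
        p_values=p_values, fdr_significant=bh_fdr(p_values, q), q=q,
        n_permutations=config.n_permutations, tails=config.tails,
        direction=config.direction, seed=config.seed)


# ---------------------------------------------------------------------------
# multiple comparisons and demographic tests
# ---------------------------------------------------------------------------

def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up flags at level ``q``.

    Rejects the hypotheses with the ``k*`` smallest p-values, where ``k*``
    is the largest k with p_(k) <= k*q/m.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    ok = sorted_p <= (np.arange(1, m + 1) * q / m)
    flags = np.zeros(m, dtype=bool)
    if ok.any():
        k_star = int(np.max(np.flatnonzero(ok))) + 1
        flags[order[:k_star]] = True
    return flags


def t_test_from_summary(mean1: float, sd1: float, n1: int,
                        mean2: float, sd2: float, n2: int) -> tuple[float, float]:
    """Pooled-variance two-sample t-test from summary statistics (two-sided p)."""
    if n1 < 2 or n2 < 2:
        raise ValidationError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValidationError("standard deviations must be positive")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    t = (mean1 - mean2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def pearson_chi2_2x2(counts) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction, 1 df."""
    c = np.asarray(counts, dtype=float)
    if c.shape != (2, 2) or np.any(c < 0) or not np.allclose(c, np.round(c)):
        raise ValidationError("counts must be a 2x2 nonnegative integer table")
    row = c.sum(axis=1)
    col = c.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValidationError("table has a zero margin")
    expected = np.outer(row, col) / c.sum()
    chi2 = float(((c - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))
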