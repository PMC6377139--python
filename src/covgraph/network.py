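"""Group association matrices and density-thresholded binary networks."""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import ValidationError, round_half_up
from .cohort import ROIVolumeTable

__all__ = [
    "AssociationMatrix",
    "DensityGrid",
    "BinaryNetwork",
    "residualize",
    "group_association_matrix",
    "threshold_at_density",
    "density_sweep",
    "ranked_positive_edges",
]


@dataclass(frozen=True)
class AssociationMatrix:
    """Per-group N x N Pearson correlation matrix over ROIs."""

    matrix: np.ndarray
    roi_names: list[str]
    group: str = ""
    n_subjects: int = 0

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError("association matrix must be square")
        if m.shape[0] != len(self.roi_names):
            raise ValidationError("roi_names length must match matrix size")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValidationError("association matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValidationError("association matrix must have unit diagonal")
        if np.any(np.abs(m) > 1 + 1e-10):
            raise ValidationError("correlations must lie in [-1, 1]")

    @property
    def n_rois(self) -> int:
        return self.matrix.shape[0]

    def to_tsv(self, path, meta_path=None) -> None:
        pd.DataFrame(self.matrix, columns=self.roi_names).to_csv(
            path, sep="\t", index=False, float_format="%.10g")
        if meta_path is not None:
            with open(meta_path, "w") as fh:
                json.dump({"group": self.group, "n_subjects": self.n_subjects,
                           "n_rois": self.n_rois,
                           "edge_sign_policy": "positive correlations only"},
                          fh, indent=2)

    @classmethod
    def from_tsv(cls, path, group: str = "", n_subjects: int = 0) -> "AssociationMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls(df.to_numpy(dtype=float), list(df.columns), group, n_subjects)


@dataclass(frozen=True)
class DensityGrid:
    """Inclusive arithmetic grid of connection densities."""

    d_min: float = 0.10
    d_max: float = 0.50
    step: float = 0.02

    def __post_init__(self):
        if not (0 < self.d_min <= self.d_max < 1):
            raise ValidationError("need 0 < d_min <= d_max < 1")
        if self.step <= 0:
            raise ValidationError("step must be positive")

    @property
    def values(self) -> np.ndarray:
        n = int(np.floor((self.d_max - self.d_min) / self.step + 1e-9)) + 1
        return np.round(self.d_min + self.step * np.arange(n), 10)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class BinaryNetwork:
    """Undirected simple graph at one connection density."""

    adjacency: np.ndarray
    density_requested: float
    density_actual: float
    roi_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValidationError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValidationError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValidationError("adjacency must have zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise ValidationError("adjacency entries must be 0/1")
        object.__setattr__(self, "adjacency", a.astype(np.uint8))
        if not self.roi_names:
            object.__setattr__(self, "roi_names",
                               [f"n{i}" for i in range(a.shape[0])])

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_list(self) -> tuple[np.ndarray, np.ndarray]:
        i, j = np.triu_indices(self.n_nodes, k=1)
        keep = self.adjacency[i, j] > 0
        return i[keep], j[keep]


def residualize(table: ROIVolumeTable, covariate_names) -> ROIVolumeTable:
    """Replace each ROI column by OLS residuals on intercept + covariates.

    The fit runs over the full sample (both groups pooled); with an empty
    covariate list this reduces to mean-centering each column.
    """
    covariate_names = list(covariate_names)
    missing = [c for c in covariate_names if c not in table.data.columns]
    if missing:
        raise ValidationError(f"covariates not in table: {missing}")
    n = len(table.data)
    if n <= len(covariate_names) + 1:
        raise ValidationError("need more subjects than covariates + 1")
    design = np.column_stack(
        [np.ones(n)] + [table.data[c].to_numpy(dtype=float) for c in covariate_names])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = []
        cols = [design[:, :1]]
        r = 1
        for k, name in enumerate(covariate_names):
            cand = np.column_stack(cols + [design[:, k + 1]])
            if np.linalg.matrix_rank(cand) == r:
                bad.append(name)
            else:
                cols.append(design[:, k + 1:k + 2])
                r += 1
        raise ValidationError(f"rank-deficient design; collinear covariates: {bad}")
    y = table.volumes()
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return table.with_volumes(y - design @ beta)


def group_association_matrix(table: ROIVolumeTable, group: str) -> AssociationMatrix:
    """Pairwise Pearson correlation over the subjects of one group."""
    x = table.volumes(group)
    if x.shape[0] < 3:
        raise ValidationError(f"group {group!r} has fewer than 3 subjects")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        bad = [table.roi_names[k] for k in np.flatnonzero(sd == 0)]
        raise ValidationError(f"constant ROI column(s) in group {group!r}: {bad}")
    m = np.corrcoef(x, rowvar=False)
    m = np.clip((m + m.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return AssociationMatrix(m, list(table.roi_names), group, x.shape[0])


def ranked_positive_edges(matrix: np.ndarray):
    """Upper-triangle pairs sorted by descending correlation.

    Ties are broken by ascending (row, column) index.  Returns
    ``(rows, cols, n_positive)`` where the first ``n_positive`` pairs have
    strictly positive correlation.
    """
    n = matrix.shape[0]
    i, j = np.triu_indices(n, k=1)
    r = matrix[i, j]
    order = np.lexsort((j, i, -r))
    n_pos = int(np.count_nonzero(r > 0))
    return i[order], j[order], n_pos


def _target_edge_count(d: float, n: int) -> int:
    return round_half_up(d * n * (n - 1) / 2.0)


def threshold_at_density(a: AssociationMatrix, d: float,
                         roi_names=None) -> BinaryNetwork:
    """Keep the m strongest positive correlations, m = round_half_up(d*N(N-1)/2).

    Negative and zero correlations are never admitted; if fewer positive
    correlations exist than requested, all positives become edges and a
    warning records the shortfall.
    """
    if not (0 < d < 1):
        raise ValidationError("density must lie in (0, 1)")
    matrix = a.matrix if isinstance(a, AssociationMatrix) else np.asarray(a, float)
    names = list(a.roi_names) if isinstance(a, AssociationMatrix) else list(roi_names or [])
    n = matrix.shape[0]
    ii, jj, n_pos = ranked_positive_edges(matrix)
    m_target = _target_edge_count(d, n)
    m = min(m_target, n_pos)
    if m < m_target:
        warnings.warn(
            f"only {n_pos} positive correlations available; requested density "
            f"{d} needs {m_target} edges", RuntimeWarning, stacklevel=2)
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[ii[:m], jj[:m]] = 1
    adj |= adj.T
    actual = 2.0 * m / (n * (n - 1)) if n > 1 else 0.0
    return BinaryNetwork(adj, d, actual, names)


def density_sweep(a: AssociationMatrix, grid: DensityGrid) -> list[BinaryNetwork]:
    """One binary network per grid density; edge sets are nested by construction."""
    matrix = a.matrix
    n = matrix.shape[0]
    ii, jj, n_pos = ranked_positive_edges(matrix)
    nets = []
    for d in grid.values:
        m_target = _target_edge_count(float(d), n)
        m = min(m_target, n_pos)
        if m < m_target:
            warnings.warn(
                f"only {n_pos} positive correlations available at density {d}",
                RuntimeWarning, stacklevel=2)
        adj = np.zeros((n, n), dtype=np.uint8)
        adj[ii[:m], jj[:m]] = 1
        adj |= adj.T
        actual = 2.0 * m / (n * (n - 1)) if n > 1 else 0.0
        nets.append(BinaryNetwork(adj, float(d), actual, list(a.roi_names)))
    return nets
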