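"""Synthetic two-group ROI-volume cohorts.

Generates subject-by-region gray-matter volume tables from multivariate
normal draws with a controllable inter-regional correlation structure,
optional planted group differences (hub weakening / module boosting) and
linear confound effects, so the downstream graph pipeline can be tested
without imaging data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._util import ValidationError

__all__ = [
    "CorrelationTarget",
    "CohortSpec",
    "ROIVolumeTable",
    "modular_correlation_target",
    "nearest_psd_repair",
    "plant_group_difference",
    "sampled_target",
    "generate_cohort",
    "default_spec",
]

#: eigenvalue floor used by the PSD repair
_EIG_FLOOR = 1e-8
#: tolerance below which a matrix counts as PSD without repair
_PSD_TOL = 1e-10

GROUPS = ("control", "patient")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationTarget:
    """Target inter-regional correlation matrix for one group.

    Parameters
    ----------
    matrix
        N x N symmetric matrix with unit diagonal, entries in [-1, 1] and
        no negative eigenvalues (beyond numerical tolerance).
    module_assignment
        Optional per-ROI module id (used only for bookkeeping).
    """

    matrix: np.ndarray
    module_assignment: np.ndarray | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError("correlation target must be a square matrix")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValidationError("correlation target must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-12):
            raise ValidationError("correlation target must have unit diagonal")
        if np.any(m < -1 - 1e-12) or np.any(m > 1 + 1e-12):
            raise ValidationError("correlation entries must lie in [-1, 1]")

    @property
    def n_rois(self) -> int:
        return self.matrix.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.matrix)[0])

    def is_psd(self, tol: float = _PSD_TOL) -> bool:
        return self.min_eigenvalue() >= -tol


@dataclass
class CohortSpec:
    """Full description of a two-group synthetic cohort.

    ``correlation_targets`` maps group name -> :class:`CorrelationTarget`;
    ``confound_model`` maps covariate name -> per-ROI coefficient vector;
    ``covariate_distributions`` maps covariate name -> sampler spec, either
    ``("normal", mean, sd)`` or ``("bernoulli", p)``.
    """

    n_per_group: tuple[int, int]
    roi_mean_volumes: np.ndarray
    roi_volume_sd: np.ndarray
    correlation_targets: dict[str, CorrelationTarget]
    confound_model: dict[str, np.ndarray] = field(default_factory=dict)
    covariate_distributions: dict[str, tuple] = field(default_factory=dict)
    seed: int = 0
    roi_names: list[str] | None = None

    def __post_init__(self):
        self.roi_mean_volumes = np.asarray(self.roi_mean_volumes, dtype=float)
        self.roi_volume_sd = np.asarray(self.roi_volume_sd, dtype=float)
        n = self.n_rois
        if self.roi_mean_volumes.shape != (n,) or self.roi_volume_sd.shape != (n,):
            raise ValidationError("per-ROI vectors must all have length n_rois")
        if np.any(self.roi_volume_sd <= 0):
            raise ValidationError("roi_volume_sd must be strictly positive")
        if len(self.n_per_group) != 2 or any(k < 1 for k in self.n_per_group):
            raise ValidationError("n_per_group must be a pair of positive integers")
        for g in GROUPS:
            if g not in self.correlation_targets:
                raise ValidationError(f"missing correlation target for group {g!r}")
            if self.correlation_targets[g].n_rois != n:
                raise ValidationError(f"correlation target for {g!r} has wrong size")
        for name, coefs in list(self.confound_model.items()):
            coefs = np.asarray(coefs, dtype=float)
            if coefs.shape != (n,):
                raise ValidationError(f"confound coefficients for {name!r} must have length n_rois")
            if name not in self.covariate_distributions:
                raise ValidationError(f"confound {name!r} has no covariate distribution")
            self.confound_model[name] = coefs
        if self.roi_names is None:
            width = len(str(n))
            self.roi_names = [f"ROI{i + 1:0{width}d}" for i in range(n)]
        if len(self.roi_names) != n:
            raise ValidationError("roi_names length must equal n_rois")

    @property
    def n_rois(self) -> int:
        return next(iter(self.correlation_targets.values())).n_rois \
            if self.correlation_targets else self.roi_mean_volumes.shape[0]

    # -- YAML round trip ----------------------------------------------------

    @classmethod
    def from_yaml(cls, path_or_stream) -> "CohortSpec":
        """Build a spec from the documented YAML schema (see README)."""
        if hasattr(path_or_stream, "read"):
            cfg = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream) as fh:
                cfg = yaml.safe_load(fh)
        return cls.from_dict(cfg)

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "CohortSpec":
        n_rois = int(cfg["n_rois"])
        mean = cfg.get("roi_mean_volumes", 5000.0)
        sd = cfg.get("roi_volume_sd", 500.0)
        mean = np.full(n_rois, float(mean)) if np.isscalar(mean) else np.asarray(mean, float)
        sd = np.full(n_rois, float(sd)) if np.isscalar(sd) else np.asarray(sd, float)
        targets = {}
        corr_cfg = cfg["correlation"]
        for g in GROUPS:
            gc = dict(corr_cfg[g])
            effect = gc.pop("effect", None)
            target = modular_correlation_target(
                n_rois=n_rois,
                n_modules=int(gc.get("n_modules", 1)),
                within_r=float(gc.get("within_r", 0.0)),
                between_r=float(gc.get("between_r", 0.0)),
            )
            if effect is not None:
                target = plant_group_difference(
                    target,
                    kind=effect["kind"],
                    magnitude=float(effect["magnitude"]),
                    target_rois=list(effect["target_rois"]),
                )
            targets[g] = target
        cov_dists = {}
        for name, dcfg in (cfg.get("covariates") or {}).items():
            kind = dcfg["dist"]
            if kind == "normal":
                cov_dists[name] = ("normal", float(dcfg["mean"]), float(dcfg["sd"]))
            elif kind == "bernoulli":
                cov_dists[name] = ("bernoulli", float(dcfg["p"]))
            else:
                raise ValidationError(f"unknown covariate distribution {kind!r}")
        confounds = {}
        for name, coefs in (cfg.get("confounds") or {}).items():
            confounds[name] = (np.full(n_rois, float(coefs))
                               if np.isscalar(coefs) else np.asarray(coefs, float))
        return cls(
            n_per_group=tuple(int(k) for k in cfg.get("n_per_group", (33, 35))),
            roi_mean_volumes=mean,
            roi_volume_sd=sd,
            correlation_targets=targets,
            confound_model=confounds,
            covariate_distributions=cov_dists,
            seed=int(cfg.get("seed", 0)),
        )


@dataclass
class ROIVolumeTable:
    """Subject x ROI volume table with group labels and optional covariates.

    Backed by a :class:`pandas.DataFrame` with columns
    ``subject_id, group, <covariates...>, <roi columns...>``.
    """

    data: pd.DataFrame
    roi_names: list[str]
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        required = ["subject_id", "group"] + self.covariate_names + self.roi_names
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValidationError(f"table is missing columns: {missing}")
        vols = self.data[self.roi_names].to_numpy(dtype=float)
        if not np.all(np.isfinite(vols)):
            raise ValidationError("volumes must be finite with no missing values")
        if self.data["subject_id"].duplicated().any():
            raise ValidationError("duplicate subject_id values")

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    @property
    def groups(self) -> list[str]:
        return list(pd.unique(self.data["group"]))

    def volumes(self, group: str | None = None) -> np.ndarray:
        """Subjects x ROIs volume matrix, optionally restricted to one group."""
        df = self.data if group is None else self.data[self.data["group"] == group]
        if group is not None and df.empty:
            raise ValidationError(f"no subjects in group {group!r}")
        return df[self.roi_names].to_numpy(dtype=float)

    def group_labels(self) -> np.ndarray:
        return self.data["group"].to_numpy()

    def with_volumes(self, new_volumes: np.ndarray) -> "ROIVolumeTable":
        df = self.data.copy()
        df[self.roi_names] = np.asarray(new_volumes, dtype=float)
        return ROIVolumeTable(df, list(self.roi_names), list(self.covariate_names))

    def with_group_labels(self, labels: Sequence[str]) -> "ROIVolumeTable":
        df = self.data.copy()
        df["group"] = list(labels)
        return ROIVolumeTable(df, list(self.roi_names), list(self.covariate_names))

    # -- I/O ----------------------------------------------------------------

    def to_tsv(self, path) -> None:
        cols = ["subject_id", "group"] + self.covariate_names + self.roi_names
        self.data[cols].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, covariates: Sequence[str] = ()) -> "ROIVolumeTable":
        """Read a table written by :meth:`to_tsv`.

        Columns other than ``subject_id``, ``group`` and the named
        ``covariates`` are taken to be ROI volumes, in file order.
        """
        df = pd.read_csv(path, sep="\t")
        covariates = list(covariates)
        rois = [c for c in df.columns
                if c not in ("subject_id", "group") and c not in covariates]
        return cls(df, rois, covariates)


# ---------------------------------------------------------------------------
# correlation-target construction
# ---------------------------------------------------------------------------

def modular_correlation_target(n_rois: int, n_modules: int,
                               within_r: float, between_r: float) -> CorrelationTarget:
    """Block-structured correlation target.

    ROIs are split into ``n_modules`` contiguous, near-equal blocks; pairs
    inside a block get ``within_r`` and pairs across blocks ``between_r``.
    The result is PSD-repaired if the requested values make it indefinite.
    """
    if n_modules < 1:
        raise ValidationError("n_modules must be >= 1")
    if n_rois < 1:
        raise ValidationError("n_rois must be >= 1")
    if not (-1 < between_r <= within_r < 1):
        raise ValidationError("need -1 < between_r <= within_r < 1")
    sizes = np.full(n_modules, n_rois // n_modules)
    sizes[: n_rois % n_modules] += 1
    assignment = np.repeat(np.arange(n_modules), sizes)
    same = assignment[:, None] == assignment[None, :]
    m = np.where(same, within_r, between_r)
    np.fill_diagonal(m, 1.0)
    target = CorrelationTarget(m, module_assignment=assignment)
    if not target.is_psd():
        repaired = nearest_psd_repair(m)
        target = CorrelationTarget(repaired.matrix, module_assignment=assignment)
    return target


def nearest_psd_repair(matrix) -> CorrelationTarget:
    """Clip eigenvalues below ``1e-8`` and renormalize to unit diagonal.

    A cheap projection onto valid correlation matrices: indefinite inputs
    become PSD, PSD inputs pass through essentially unchanged.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError("matrix must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValidationError("matrix must be symmetric")
    w, v = np.linalg.eigh((m + m.T) / 2.0)
    w = np.clip(w, _EIG_FLOOR, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    fixed = (fixed + fixed.T) / 2.0
    np.fill_diagonal(fixed, 1.0)
    np.clip(fixed, -1.0, 1.0, out=fixed)
    return CorrelationTarget(fixed)


def plant_group_difference(base: CorrelationTarget, kind: str,
                           magnitude: float, target_rois) -> CorrelationTarget:
    """Modify a target to create a known group difference.

    ``hub_weakening`` multiplies every correlation incident to a target ROI
    by ``1 - magnitude`` per incident endpoint (so correlations between two
    target ROIs are scaled twice); ``module_boost`` raises correlations
    among the target ROIs by ``magnitude`` (capped below 1).  The result is
    PSD-repaired.

    Weakening a large target set concentrates thresholded edges onto the
    unweakened ROIs, which makes the resulting networks hub-dependent and
    hence less resilient to betweenness-targeted attack.
    """
    target_rois = np.asarray(list(target_rois), dtype=int)
    if target_rois.size == 0:
        raise ValidationError("target_rois must be non-empty")
    if not (0 < magnitude <= 1):
        raise ValidationError("magnitude must lie in (0, 1]")
    n = base.n_rois
    if np.any(target_rois < 0) or np.any(target_rois >= n):
        raise ValidationError("target_rois out of range")
    m = base.matrix.copy()
    in_set = np.zeros(n, dtype=bool)
    in_set[target_rois] = True
    if kind == "hub_weakening":
        scale = np.where(in_set, 1.0 - magnitude, 1.0)
        factor = np.outer(scale, scale)
        np.fill_diagonal(factor, 1.0)
        m *= factor
    elif kind == "module_boost":
        among = in_set[:, None] & in_set[None, :]
        np.fill_diagonal(among, False)
        m[among] = np.minimum(m[among] + magnitude, 0.99)
    else:
        raise ValidationError(f"unknown effect kind {kind!r}")
    repaired = nearest_psd_repair(m)
    return CorrelationTarget(repaired.matrix, module_assignment=base.module_assignment)


def sampled_target(base: CorrelationTarget, n: int = 4000,
                   seed: int = 0) -> CorrelationTarget:
    """Empirical correlation of a large multivariate-normal draw from ``base``.

    Block-structured targets have exactly tied off-diagonal entries, which
    makes rank-based density thresholding degenerate (ties resolved purely
    by ROI index).  A large-sample realization keeps the structure but
    breaks every tie, giving a realistic 'noiseless-limit' target.
    """
    if n < base.n_rois + 2:
        raise ValidationError("sample size too small for a full-rank correlation")
    rng = np.random.default_rng(seed)
    x = rng.multivariate_normal(np.zeros(base.n_rois), base.matrix, size=n,
                                method="eigh")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationTarget(r, base.module_assignment)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _sample_covariates(dists: Mapping[str, tuple], n: int,
                       rng: np.random.Generator) -> dict[str, np.ndarray]:
    out = {}
    for name in dists:  # dict order is fixed, so the stream is reproducible
        spec = dists[name]
        if spec[0] == "normal":
            out[name] = rng.normal(spec[1], spec[2], size=n)
        elif spec[0] == "bernoulli":
            out[name] = rng.binomial(1, spec[1], size=n).astype(float)
        else:
            raise ValidationError(f"unknown covariate distribution {spec[0]!r}")
    return out


def generate_cohort(spec: CohortSpec) -> ROIVolumeTable:
    """Draw a full two-group cohort according to ``spec``.

    Each group's volumes are multivariate normal with the group's target
    correlation; confound contributions are added linearly.  Group draws use
    independent child streams of the master seed keyed by group index, so
    changing one group's size never perturbs the other group's data.
    """
    frames = []
    for gi, group in enumerate(GROUPS):
        target = spec.correlation_targets[group]
        if not target.is_psd(tol=1e-8):
            raise ValidationError(
                f"correlation target for {group!r} is not PSD; run nearest_psd_repair first")
        n = spec.n_per_group[gi]
        cov = target.matrix * np.outer(spec.roi_volume_sd, spec.roi_volume_sd)
        rng_vol = np.random.default_rng([spec.seed, gi, 0])
        rng_cov = np.random.default_rng([spec.seed, gi, 1])
        draws = rng_vol.multivariate_normal(spec.roi_mean_volumes, cov, size=n, method="eigh")
        covariates = _sample_covariates(spec.covariate_distributions, n, rng_cov)
        for name, coefs in spec.confound_model.items():
            draws = draws + np.outer(covariates[name], coefs)
        frame = pd.DataFrame(
            {"subject_id": [f"{group[:3]}{i + 1:03d}" for i in range(n)], "group": group})
        for name in spec.covariate_distributions:
            frame[name] = covariates[name]
        frame[spec.roi_names] = draws
        frames.append(frame)
    data = pd.concat(frames, ignore_index=True)
    return ROIVolumeTable(data, list(spec.roi_names),
                          list(spec.covariate_distributions))


def default_spec(seed: int = 0) -> CohortSpec:
    """Cohort mirroring the emulated study scale: 33 vs 35 subjects, 90 ROIs,
    age ~ N(27, 7), sex ~ Bernoulli(0.75)."""
    n_rois = 90
    target = modular_correlation_target(n_rois, n_modules=6, within_r=0.5, between_r=0.15)
    return CohortSpec(
        n_per_group=(35, 33),  # (control, patient)
        roi_mean_volumes=np.full(n_rois, 5000.0),
        roi_volume_sd=np.full(n_rois, 500.0),
        correlation_targets={"control": target, "patient": target},
        covariate_distributions={"age": ("normal", 27.0, 7.0),
                                 "sex": ("bernoulli", 0.75)},
        seed=seed,
    )
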