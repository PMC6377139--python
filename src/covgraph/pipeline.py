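"""Configuration-driven orchestration of the full analysis.

Stages: simulate/load -> association matrices -> metric curves ->
resilience curves -> permutation comparisons -> Markdown report.  Every
stage writes plain-text artifacts (TSV/JSON) into the output directory and
the manifest records seeds, options and a config hash so reruns are
byte-identical.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._util import ValidationError, trapezoid_auc
from .cohort import CohortSpec, ROIVolumeTable, generate_cohort
from .inference import (
    PermutationConfig,
    compare_global_metric,
    compare_regional_clustering,
    compare_resilience,
)
from .metrics import metric_curve, normalized_metrics, random_ensemble
from .network import DensityGrid, density_sweep, group_association_matrix, residualize
from .resilience import AttackSchedule, random_failure_curve, targeted_attack_curve

__all__ = ["RunConfig", "run_pipeline", "report"]

GROUPS = ("control", "patient")


@dataclass
class RunConfig:
    """Everything a run needs; defaults mirror the reference workflow
    (density grid 0.10-0.50 step 0.02, 20 random networks, 1000
    permutations, FDR q = 0.05)."""

    input_table: str | None = None          # TSV path; None -> simulate
    covariates: list[str] = field(default_factory=list)
    cohort: dict | None = None              # CohortSpec dict when simulating
    residualize_covariates: bool = False
    d_min: float = 0.10
    d_max: float = 0.50
    d_step: float = 0.02
    disconnected_policy: str = "connected_pairs"
    n_random_networks: int = 20
    attack_kinds: list[str] = field(
        default_factory=lambda: ["targeted_betweenness", "random"])
    n_random_sequences: int = 50
    n_permutations: int = 1000
    tails: str = "one"
    direction: str = "control_gt_patient"
    fdr_q: float = 0.05
    compare_metrics: list[str] = field(
        default_factory=lambda: ["clustering", "path_length"])
    run_resilience: bool = True
    run_regional: bool = True
    seed: int = 0
    out_dir: str = "covgraph_out"

    def __post_init__(self):
        if not (0 < self.d_min <= self.d_max < 1):
            raise ValidationError("need 0 < d_min <= d_max < 1")
        if self.input_table is None and self.cohort is None:
            raise ValidationError("config needs either input_table or a cohort block")

    @property
    def grid(self) -> DensityGrid:
        return DensityGrid(self.d_min, self.d_max, self.d_step)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**cfg)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_table(config: RunConfig) -> ROIVolumeTable:
    if config.input_table is not None:
        return ROIVolumeTable.from_tsv(config.input_table, config.covariates)
    cohort_cfg = dict(config.cohort)
    cohort_cfg.setdefault("seed", config.seed)
    spec = CohortSpec.from_dict(cohort_cfg)
    return generate_cohort(spec)


def _write_curve_tsv(path: Path, rows: list[dict]) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "covgraph_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "artifacts": {},
        "stages": [],
    }

    def stage(name):
        manifest["stages"].append(name)

    try:
        table = _load_table(config)
        stage("load")
        if config.residualize_covariates and config.covariates:
            table = residualize(table, config.covariates)
            stage("residualize")
        table_path = out / "roi_volumes.tsv"
        table.to_tsv(table_path)
        manifest["artifacts"]["roi_volumes"] = table_path.name

        grid = config.grid
        matrices = {}
        for group in GROUPS:
            a = group_association_matrix(table, group)
            matrices[group] = a
            a.to_tsv(out / f"association_{group}.tsv",
                     out / f"association_{group}.json")
            manifest["artifacts"][f"association_{group}"] = f"association_{group}.tsv"
        stage("association")

        # metric curves per group (with normalized metrics at each density)
        curve_rows = []
        auc_summary: dict = {g: {} for g in GROUPS}
        for group, a in matrices.items():
            nets = density_sweep(a, grid)
            for name in ("clustering", "path_length"):
                mc = metric_curve(nets, name,
                                  disconnected_policy=config.disconnected_policy)
                auc_summary[group][name] = mc.auc
                for d, v in zip(mc.densities, mc.values):
                    curve_rows.append({"metric": name, "group": group,
                                       "density": d, "value": v})
            gammas, lambdas, sigmas = [], [], []
            for i, net in enumerate(nets):
                ens = random_ensemble(net, config.n_random_networks,
                                      seed=config.seed + 7919 * i)
                gm = normalized_metrics(net, ens, config.disconnected_policy)
                for label, val, acc in (("gamma", gm.gamma, gammas),
                                        ("lambda", gm.lambda_, lambdas),
                                        ("sigma", gm.sigma, sigmas)):
                    acc.append(np.nan if val is None else val)
                    curve_rows.append({"metric": label, "group": group,
                                       "density": net.density_requested,
                                       "value": acc[-1]})
            for label, acc in (("gamma", gammas), ("lambda", lambdas),
                               ("sigma", sigmas)):
                vals = np.asarray(acc)
                auc_summary[group][label] = (
                    float(trapezoid_auc(vals, grid.values))
                    if not np.any(np.isnan(vals)) else None)
        _write_curve_tsv(out / "metric_curves.tsv", curve_rows)
        manifest["artifacts"]["metric_curves"] = "metric_curves.tsv"
        stage("metrics")

        if config.run_resilience:
            res_rows = []
            for group, a in matrices.items():
                nets = density_sweep(a, grid)
                for i, net in enumerate(nets):
                    curves = {}
                    if "targeted_betweenness" in config.attack_kinds:
                        curves["targeted_betweenness"] = targeted_attack_curve(net)
                    if "random" in config.attack_kinds:
                        sched = AttackSchedule(
                            kind="random",
                            n_random_sequences=config.n_random_sequences,
                            seed=config.seed + 104729 * i)
                        curves["random"] = random_failure_curve(net, sched)
                    for kind, rc in curves.items():
                        auc_summary[group][f"attack_auc_{kind}_d{net.density_requested:g}"] = rc.auc
                        for f, v in zip(rc.fraction_removed, rc.relative_lcc):
                            res_rows.append({"group": group, "kind": kind,
                                             "density": net.density_requested,
                                             "fraction_removed": f,
                                             "relative_lcc": v})
            _write_curve_tsv(out / "resilience_curves.tsv", res_rows)
            manifest["artifacts"]["resilience_curves"] = "resilience_curves.tsv"
            stage("resilience")

        with open(out / "auc_summary.json", "w") as fh:
            json.dump(auc_summary, fh, indent=2)
        manifest["artifacts"]["auc_summary"] = "auc_summary.json"

        # permutation comparisons
        perm_cfg = PermutationConfig(
            n_permutations=config.n_permutations, tails=config.tails,
            seed=config.seed, statistic="per_density_difference",
            direction=config.direction)
        comparisons = {}
        for name in config.compare_metrics:
            r = compare_global_metric(table, name, grid, perm_cfg,
                                      config.disconnected_policy)
            comparisons[name] = r
        if config.run_resilience:
            for kind in config.attack_kinds:
                r = compare_resilience(table, grid, kind, perm_cfg,
                                       config.n_random_sequences)
                comparisons[r.metric_name] = r
        comp_json = {}
        for name, r in comparisons.items():
            comp_json[name] = {
                "observed_auc_difference": r.observed,
                "p_value": r.p_value,
                "per_density_p": None if r.per_density_p is None
                                 else list(map(float, r.per_density_p)),
                "n_permutations": r.n_permutations,
                "tails": r.tails,
                "direction": r.direction,
                "seed": r.seed,
                "n_redraws": r.n_redraws,
                "control_curve": list(map(float, r.control_curve)),
                "patient_curve": list(map(float, r.patient_curve)),
                "densities": list(map(float, r.densities)),
            }
        with open(out / "comparisons.json", "w") as fh:
            json.dump(comp_json, fh, indent=2)
        manifest["artifacts"]["comparisons"] = "comparisons.json"
        stage("compare")

        if config.run_regional:
            reg = compare_regional_clustering(table, grid, perm_cfg,
                                              q=config.fdr_q)
            reg_df = pd.DataFrame({
                "roi": reg.roi_names,
                "observed_diff": reg.observed_diffs,
                "p_value": reg.p_values,
                "fdr_significant": reg.fdr_significant,
            }).sort_values(["p_value", "roi"], kind="stable")
            reg_df.to_csv(out / "regional_clustering.tsv", sep="\t",
                          index=False, float_format="%.10g")
            manifest["artifacts"]["regional_clustering"] = "regional_clustering.tsv"
            stage("regional")
    except Exception as err:
        failed_stage = manifest["stages"][-1] if manifest["stages"] else "load"
        raise RuntimeError(
            f"pipeline failed after stage {failed_stage!r}: {err}") from err

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def report(out_dir) -> str:
    """Assemble a Markdown report from a completed run's artifacts.

    The report only formats numbers already on disk; it computes nothing.
    Missing artifacts are listed rather than fatal.
    """
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise ValidationError(f"no manifest.json under {out}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    lines = ["# covgraph run report", ""]
    cfg = manifest["config"]
    lines += [
        f"- covgraph version: {manifest['covgraph_version']}",
        f"- config hash: `{manifest['config_hash']}`",
        f"- master seed: {manifest['seed']}",
        f"- density grid: {cfg['d_min']}-{cfg['d_max']} step {cfg['d_step']}",
        f"- disconnected-path policy: {cfg['disconnected_policy']}",
        f"- permutations: {cfg['n_permutations']} ({cfg['tails']}-tailed, "
        f"direction {cfg['direction']})",
        f"- FDR q: {cfg['fdr_q']}",
        "",
    ]
    missing = []

    def have(key):
        name = manifest["artifacts"].get(key)
        if name and (out / name).exists():
            return out / name
        missing.append(key)
        return None

    for group in GROUPS:
        if have(f"association_{group}"):
            lines.append(f"## Association matrix: {group}")
            meta = out / f"association_{group}.json"
            if meta.exists():
                with open(meta) as fh:
                    m = json.load(fh)
                lines.append(f"- {m['n_rois']} ROIs, n = {m['n_subjects']} subjects "
                             f"({m['edge_sign_policy']})")
            lines.append(f"- file: `association_{group}.tsv`")
            lines.append("")

    p = have("comparisons")
    if p:
        with open(p) as fh:
            comp = json.load(fh)
        lines.append("## Group comparisons (AUC over the density grid)")
        lines.append("")
        lines.append("| metric | observed AUC diff (control - patient) | p |")
        lines.append("|---|---|---|")
        for name, r in comp.items():
            lines.append(f"| {name} | {r['observed_auc_difference']:+.4f} "
                         f"| {r['p_value']:.4f} |")
        lines.append("")

    p = have("regional_clustering") if cfg.get("run_regional", True) else None
    if p:
        reg = pd.read_csv(p, sep="\t")
        lines.append("## Regional clustering (sorted by p, then ROI)")
        lines.append("")
        lines.append("| ROI | observed diff | p | FDR significant |")
        lines.append("|---|---|---|---|")
        for _, row in reg.iterrows():
            lines.append(f"| {row['roi']} | {row['observed_diff']:+.4f} "
                         f"| {row['p_value']:.4f} | {bool(row['fdr_significant'])} |")
        lines.append("")

    if cfg.get("run_resilience", True):
        p = have("resilience_curves")
        if p:
            lines.append("## Resilience")
            lines.append(f"- per-density attack curves: `{p.name}`")
            lines.append("")

    if missing:
        lines.append("## Missing artifacts")
        lines += [f"- {k}" for k in missing]
        lines.append("")
    text = "\n".join(lines)
    with open(out / "report.md", "w") as fh:
        fh.write(text)
    return text
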