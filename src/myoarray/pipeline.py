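"""End-to-end orchestration: simulate -> quantify -> normalize -> signatures
-> stats -> cluster -> classify -> report.

Every intermediate artifact is written as CSV into the output directory and
the run report (JSON) embeds all seeds, the config hash, and the
performance numbers of the configured clustering tasks and interval rules,
so an identical configuration reproduces an identical report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

from . import __version__
from .classify import default_rules, evaluate_panel, load_rules, rule_recall
from .cluster import cluster_performance, cut_tree, euclidean_distances, wpgma_linkage
from .containers import ExpressionMatrix
from .io import write_expression_csv, write_newick, write_spot_csv
from .panel import CLUSTER_PRESETS, default_panel
from .quantify import quantify_table, quantified_to_matrix
from .signatures import append_signatures, fold_of_control, log2_relative
from .simulate import (
    ArrayLayoutSpec,
    default_cohort_spec,
    default_curve_params,
    load_cohort_spec,
    simulate_cohort,
    simulate_spot_table,
)
from .stats import stats_table

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("myoarray.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one full pipeline run."""

    outdir: str
    cohort_path: str | None = None  # None -> packaged default cohort
    rules_path: str | None = None  # None -> packaged default rules
    control_label: str | None = None  # None -> cohort's flagged control
    cluster_tasks: tuple[str, ...] = tuple(CLUSTER_PRESETS)
    replicates_per_sample: int = 4
    technical_cv_percent: float = 8.6
    mc_draws: int = 100_000
    seed: int = 0
    log2_floor: float = 0.01

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- validation before any stage runs
    cohort = (
        load_cohort_spec(config.cohort_path)
        if config.cohort_path
        else default_cohort_spec()
    ).with_seed(config.seed)
    control = config.control_label or cohort.control_label
    if control not in {g.group_name for g in cohort.groups}:
        raise ValueError(f"control label {control!r} not among cohort groups")
    rules = load_rules(config.rules_path) if config.rules_path else default_rules()
    for task in config.cluster_tasks:
        if task not in CLUSTER_PRESETS:
            raise ValueError(f"unknown clustering preset {task!r}")
    panel = default_panel()
    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seeds": {
            "cohort": config.seed,
            "array": config.seed + 1,
            "stats": config.seed + 2,
        },
        "stages": {},
    }

    def stage(name: str):
        log.info("stage %s", name)
        return report["stages"].setdefault(name, {})

    # --- simulate cohort (fold-of-control scale ground truth)
    info = stage("simulate_cohort")
    truth = simulate_cohort(cohort, panel)
    write_expression_csv(truth, outdir / "cohort_truth.csv")
    info["n_samples"] = len(truth.sample_ids)

    # --- simulate arrays for the 19 assayed markers and quantify them
    info = stage("quantify")
    layout = ArrayLayoutSpec(
        replicates_per_sample=config.replicates_per_sample,
        technical_cv_percent=config.technical_cv_percent,
        seed=config.seed + 1,
    )
    marker_truth = truth.subset_markers(panel.marker_names)
    spots = simulate_spot_table(
        marker_truth, layout, default_curve_params(panel.marker_names)
    )
    write_spot_csv(spots, outdir / "spots.csv")
    quantified, mean_scv = quantify_table(spots)
    calibrated = quantified_to_matrix(quantified)
    write_expression_csv(calibrated, outdir / "calibrated.csv")
    info["n_spots"] = len(spots)
    info["array_mean_scv_percent"] = mean_scv

    # --- normalize and derive signatures
    info = stage("signatures")
    folds = fold_of_control(calibrated, control)
    with_sig = append_signatures(folds)
    write_expression_csv(with_sig, outdir / "expression_signatures.csv")
    info["markers"] = list(with_sig.markers)

    # --- group statistics vs control
    info = stage("stats")
    table = stats_table(
        with_sig,
        control,
        method="dunnett",
        mc_draws=config.mc_draws,
        seed=config.seed + 2,
    )
    table.to_csv(outdir / "stats.csv", index=False)
    info["n_comparisons"] = len(table)
    info["significant_0p05"] = int((table["p_adjusted"] < 0.05).sum())

    # --- clustering tasks on log2-relative profiles
    info = stage("cluster")
    for task in config.cluster_tasks:
        preset = CLUSTER_PRESETS[task]
        subset = with_sig.subset_classes(list(preset["groups"]))
        logged = log2_relative(subset, control, floor=config.log2_floor)
        # a sample with an undefined ratio (denominator quantified to zero)
        # has no position in marker space; exclude it and record it
        complete = logged.data[list(preset["markers"])].notna().all(axis=1)
        excluded = [str(s) for s in logged.data.index[~complete]]
        if excluded:
            log.warning("cluster task %s: excluding %d samples with "
                        "missing values: %s", task, len(excluded), excluded)
            logged = ExpressionMatrix(
                logged.data.loc[complete],
                logged.classes.loc[complete],
                logged.units,
                dict(logged.flags),
            )
        dist = euclidean_distances(logged, list(preset["markers"]))
        linkage = wpgma_linkage(dist)
        labels = cut_tree(linkage, int(preset["k"]))
        perf = cluster_performance(labels, logged.classes, control)
        write_newick(linkage, outdir / f"cluster_{task}.nwk")
        info[task] = {
            "k": int(preset["k"]),
            "excluded_samples": excluded,
            "markers": list(preset["markers"]),
            "sensitivity_percent": perf.sensitivity_percent,
            "precision_percent": perf.precision_percent,
            "specificity_percent": perf.specificity_percent,
            "pooled_pathologic_sensitivity": perf.pooled_pathologic_sensitivity,
            "pooled_control_specificity": perf.pooled_control_specificity,
        }

    # --- interval rules
    info = stage("classify")
    for rule in rules:
        if rule.disease not in {g.group_name for g in cohort.groups}:
            continue
        counts, sensitivity = evaluate_panel(with_sig, [rule], rule.disease)
        info[rule.disease] = {
            "tp": counts.tp,
            "fp": counts.fp,
            "fn": counts.fn,
            "tn": counts.tn,
            "excluded": counts.excluded,
            "sensitivity_tp_over_tp_fp": sensitivity,
            "recall_tp_over_tp_fn": rule_recall(counts),
        }

    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
    return report
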