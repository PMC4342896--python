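"""Replicated in-silico experiments on the packaged cohort summaries.

These functions re-run the two published evaluation designs on synthetic
cohorts drawn from the group summaries, averaging over many seeded
replicates:

* :func:`clustering_experiment` -- simulate the groups of one clustering
  preset, transform to log2-relative expression, cluster with
  Euclidean/WPGMA, cut at k, and score the cluster-to-class mapping.
* :func:`interval_rule_experiment` -- draw target-disease samples uniformly
  inside a rule's printed intervals and controls from the control group
  summaries, then score the rule's TP/(TP+FP) sensitivity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import RangeRule, evaluate_panel
from .cluster import cluster_performance, cut_tree, euclidean_distances, wpgma_linkage
from .containers import ExpressionMatrix
from .panel import CLUSTER_PRESETS, Compartment, MarkerPanel
from .signatures import DEFAULT_LOG2_FLOOR, log2_relative
from .simulate import CohortSpec, GroupSpec, default_cohort_spec, simulate_cohort

__all__ = ["clustering_experiment", "interval_rule_experiment"]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds below 2**31, reproducible from ``seed``."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def clustering_experiment(
    preset: str | dict,
    *,
    cohort: CohortSpec | None = None,
    n_replicates: int = 200,
    seed: int = 0,
    floor: float = DEFAULT_LOG2_FLOOR,
    linkage_method: str = "wpgma",
) -> dict:
    """Mean classification metrics over replicated simulated cohorts.

    ``preset`` is a key of :data:`myoarray.panel.CLUSTER_PRESETS` or an
    explicit mapping with ``markers``, ``groups`` and ``k``. Returns mean
    per-class sensitivity (recall convention) and precision, control
    specificity, and the pooled pathologic sensitivity/specificity,
    averaged over ``n_replicates`` independent cohorts.
    """
    if isinstance(preset, str):
        preset = CLUSTER_PRESETS[preset]
    markers = list(preset["markers"])
    groups = list(preset["groups"])
    k = int(preset["k"])
    base = cohort or default_cohort_spec()
    spec = base.subset(groups)
    control = spec.control_label

    sums: dict[str, float] = {}
    counts: dict[str, int] = {}

    def add(key: str, value: float) -> None:
        if np.isnan(value):
            return
        sums[key] = sums.get(key, 0.0) + value
        counts[key] = counts.get(key, 0) + 1

    for rep_seed in _spawn_seeds(seed, n_replicates):
        expr = simulate_cohort(spec.with_seed(rep_seed))
        logged = log2_relative(expr, control, floor=floor)
        dist = euclidean_distances(logged, markers)
        linkage = wpgma_linkage(dist, method=linkage_method)
        labels = cut_tree(linkage, k)
        perf = cluster_performance(labels, logged.classes, control)
        for cls, value in perf.sensitivity_percent.items():
            add(f"sensitivity_{cls}", value)
        for cls, value in perf.precision_percent.items():
            add(f"precision_{cls}", value)
        add("specificity_control", perf.specificity_percent)
        add("pooled_pathologic_sensitivity", perf.pooled_pathologic_sensitivity)
        add("pooled_control_specificity", perf.pooled_control_specificity)
    means = {key: sums[key] / counts[key] for key in sums}
    means["n_replicates"] = n_replicates
    means["n_samples"] = sum(g.n for g in spec.groups)
    return means


def interval_rule_experiment(
    rule: RangeRule,
    *,
    n_target: int = 6,
    cohort: CohortSpec | None = None,
    n_replicates: int = 200,
    seed: int = 0,
) -> dict:
    """Mean TP/(TP+FP) sensitivity of one interval rule.

    Target samples are drawn uniformly inside the rule's two intervals;
    control samples are drawn from the control group's summaries for the
    two columns the rule reads. Averaged over ``n_replicates`` cohorts.
    """
    base = cohort or default_cohort_spec()
    control_group = next(g for g in base.groups if g.control)
    columns = ["bF1_LDHA", rule.extra_marker]
    two_col_panel = MarkerPanel(
        markers=(
            ("bF1_LDHA", Compartment.CYTOPLASMIC),
            (rule.extra_marker, Compartment.CYTOPLASMIC),
        ),
        derived_ratios={},
    )
    sens_sum = 0.0
    sens_n = 0
    for rep_seed in _spawn_seeds(seed, n_replicates):
        rng = np.random.default_rng(rep_seed)
        target = np.column_stack(
            [
                rng.uniform(*rule.ratio_interval, size=n_target),
                rng.uniform(*rule.extra_interval, size=n_target),
            ]
        )
        ctrl_spec = CohortSpec(
            (
                GroupSpec(
                    control_group.group_name,
                    control_group.n,
                    {c: control_group.per_marker[c] for c in columns},
                    control=True,
                ),
            ),
            seed=rep_seed,
            value_floor=base.value_floor,
        )
        controls = simulate_cohort(ctrl_spec, two_col_panel)
        data = pd.DataFrame(
            np.vstack([target, controls.data[columns].to_numpy()]),
            columns=columns,
            index=[f"{rule.disease}_{i + 1:02d}" for i in range(n_target)]
            + list(controls.data.index),
        )
        classes = pd.Series(
            [rule.disease] * n_target + [control_group.group_name] * control_group.n,
            index=data.index,
        )
        expr = ExpressionMatrix(data, classes, units="fold_of_control")
        counts, sensitivity = evaluate_panel(expr, [rule], rule.disease)
        if not np.isnan(sensitivity):
            sens_sum += sensitivity
            sens_n += 1
    return {
        "mean_sensitivity": sens_sum / sens_n if sens_n else float("nan"),
        "n_replicates": n_replicates,
        "n_samples": n_target + control_group.n,
    }
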