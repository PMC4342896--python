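"""Interval-rule disease classifier on bioenergetic signatures.

A disease rule calls a sample positive when its bF1/LDHA ratio falls in a
closed interval AND one additional marker falls in a second closed
interval (fold-of-control units). Rule quality is summarized two ways:
``rule_sensitivity`` follows the published convention
TP / (TP + FP) * 100 (conventionally called precision), and the recall
TP / (TP + FN) * 100 is reported separately as ``rule_recall``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd
import yaml

from .containers import ExpressionMatrix

__all__ = [
    "RangeRule",
    "ConfusionCounts",
    "apply_rule",
    "rule_sensitivity",
    "rule_recall",
    "evaluate_panel",
    "default_rules",
    "load_rules",
]

RATIO_COLUMN = "bF1_LDHA"


@dataclass(frozen=True)
class RangeRule:
    """Closed-interval rule for one disease."""

    disease: str
    ratio_interval: tuple[float, float]
    extra_marker: str
    extra_interval: tuple[float, float]

    def __post_init__(self) -> None:
        for lo, hi in (self.ratio_interval, self.extra_interval):
            if lo > hi:
                raise ValueError(f"rule {self.disease!r}: interval [{lo}, {hi}] empty")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    excluded: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def apply_rule(sample: pd.Series, rule: RangeRule) -> bool | None:
    """True iff both values fall inside their closed intervals.

    Returns None when a required value is missing; callers must count the
    sample as excluded rather than silently dropping it.
    """
    for column in (RATIO_COLUMN, rule.extra_marker):
        if column not in sample.index or pd.isna(sample[column]):
            return None
    lo, hi = rule.ratio_interval
    in_ratio = lo <= float(sample[RATIO_COLUMN]) <= hi
    lo, hi = rule.extra_interval
    in_extra = lo <= float(sample[rule.extra_marker]) <= hi
    return in_ratio and in_extra


def rule_sensitivity(counts: ConfusionCounts) -> float:
    """Published convention: 100 * TP / (TP + FP); NaN when nothing called."""
    called = counts.tp + counts.fp
    if called == 0:
        return float("nan")
    return 100.0 * counts.tp / called


def rule_recall(counts: ConfusionCounts) -> float:
    """Conventional recall: 100 * TP / (TP + FN); NaN with no positives."""
    positives = counts.tp + counts.fn
    if positives == 0:
        return float("nan")
    return 100.0 * counts.tp / positives


def evaluate_panel(
    expr: ExpressionMatrix,
    rules: list[RangeRule],
    target_class: str,
    *,
    negatives: str = "all",
) -> tuple[ConfusionCounts, float]:
    """Confusion counts and TP/(TP+FP) sensitivity for one disease.

    A sample is called positive when it matches any rule for
    ``target_class``. ``negatives`` selects which non-target samples can
    contribute false positives: ``"all"`` (default) or ``"controls_only"``
    with the control label supplied as ``negatives="controls_only:CTR"``.
    """
    rules = [r for r in rules if r.disease == target_class]
    if not rules:
        raise ValueError(f"no rules for target class {target_class!r}")
    labels = set(expr.classes)
    if target_class not in labels:
        raise ValueError(f"target class {target_class!r} absent from cohort")
    if len(labels) < 2:
        raise ValueError("cohort must contain at least one non-target class")

    if negatives == "all":
        keep = pd.Series(True, index=expr.data.index)
    elif negatives.startswith("controls_only:"):
        control = negatives.split(":", 1)[1]
        keep = expr.classes.isin([target_class, control])
    else:
        raise ValueError(f"unknown negatives policy {negatives!r}")

    tp = fp = fn = tn = excluded = 0
    for sample_id in expr.data.index[keep]:
        row = expr.data.loc[sample_id]
        matches = [apply_rule(row, rule) for rule in rules]
        if any(m is None for m in matches):
            excluded += 1
            continue
        called = any(matches)
        is_target = expr.classes.loc[sample_id] == target_class
        if called and is_target:
            tp += 1
        elif called:
            fp += 1
        elif is_target:
            fn += 1
        else:
            tn += 1
    counts = ConfusionCounts(tp, fp, fn, tn, excluded)
    return counts, rule_sensitivity(counts)


def load_rules(source) -> list[RangeRule]:
    """Rules from a YAML path or parsed mapping (``rules:`` section)."""
    if isinstance(source, dict):
        config = source
    else:
        with open(source, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    rules = []
    for disease, entry in config["rules"].items():
        rules.append(
            RangeRule(
                disease=disease,
                ratio_interval=tuple(float(v) for v in entry["ratio_interval"]),
                extra_marker=str(entry["extra_marker"]),
                extra_interval=tuple(float(v) for v in entry["extra_interval"]),
            )
        )
    return rules


def default_rules() -> list[RangeRule]:
    """The four packaged disease rules (DMD, BMD, NCL, LGMD2C)."""
    ref = resources.files("myoarray.data").joinpath("range_rules.yaml")
    with ref.open("r") as fh:
        return load_rules(yaml.safe_load(fh))
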