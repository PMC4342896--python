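"""Fold-of-control normalization, log2-relative transform, signature ratios.

Expression values are referenced to the control group: fold of control
divides by the control mean per marker, and the clustering input is the
log2 of each sample relative to that mean (with a small floor so that a
truly absent protein, e.g. myophosphorylase in glycogenosis type V, stays
finite and clusterable). The bioenergetic signature ratios are computed
per sample: bF1/GAPDH, the BEC index (bF1/Hsp60)/GAPDH, and bF1/LDHA.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = [
    "fold_of_control",
    "log2_relative",
    "compute_signatures",
    "SIGNATURE_REQUIRED_MARKERS",
]

#: Default floor (fold units) applied before taking log2.
DEFAULT_LOG2_FLOOR = 0.01

SIGNATURE_REQUIRED_MARKERS = ("bF1", "Hsp60", "GAPDH", "LDHA")


def _control_means(expr: ExpressionMatrix, control_label: str) -> pd.Series:
    controls = expr.group_values(control_label)
    if controls.empty:
        raise ValueError(f"no samples with control label {control_label!r}")
    return controls.mean(axis=0)


def fold_of_control(expr: ExpressionMatrix, control_label: str) -> ExpressionMatrix:
    """Divide every value by the control-group mean of its marker.

    Markers whose control mean is zero cannot be normalized; they are
    dropped and recorded under the ``unnormalizable`` flag.
    """
    means = _control_means(expr, control_label)
    bad = list(means.index[means <= 0])
    keep = [m for m in expr.markers if m not in bad]
    data = expr.data[keep] / means[keep]
    flags = dict(expr.flags)
    if bad:
        flags["unnormalizable"] = bad
    return ExpressionMatrix(data, expr.classes.copy(), "fold_of_control", flags)


def log2_relative(
    expr: ExpressionMatrix,
    control_label: str,
    floor: float = DEFAULT_LOG2_FLOOR,
) -> ExpressionMatrix:
    """log2 of each value relative to the control mean, floored below.

    value -> log2(max(value, floor) / control_mean). The floor guards
    exact zeros; it must be positive.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    means = _control_means(expr, control_label)
    if (means <= 0).any():
        bad = list(means.index[means <= 0])
        raise ValueError(f"control mean is zero for markers {bad}")
    data = np.log2(expr.data.clip(lower=floor) / means)
    return ExpressionMatrix(data, expr.classes.copy(), "log2_relative", dict(expr.flags))


def compute_signatures(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-sample bioenergetic signature ratios.

    Returns a DataFrame indexed by sample with columns ``BEC``
    ((bF1/Hsp60)/GAPDH), ``bF1_GAPDH`` and ``bF1_LDHA``. Zero denominators
    yield NaN (missing), never infinity.
    """
    missing = [m for m in SIGNATURE_REQUIRED_MARKERS if m not in expr.markers]
    if missing:
        raise KeyError(f"signature markers missing from matrix: {missing}")

    def safe_div(num: pd.Series, den: pd.Series) -> pd.Series:
        return num.where(den != 0).div(den.where(den != 0))

    bf1 = expr.data["bF1"]
    out = pd.DataFrame(index=expr.data.index)
    out["BEC"] = safe_div(safe_div(bf1, expr.data["Hsp60"]), expr.data["GAPDH"])
    out["bF1_GAPDH"] = safe_div(bf1, expr.data["GAPDH"])
    out["bF1_LDHA"] = safe_div(bf1, expr.data["LDHA"])
    return out


def append_signatures(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Matrix with the three ratio columns appended (existing ones replaced)."""
    ratios = compute_signatures(expr)
    data = expr.data.copy()
    for col in ratios.columns:
        data[col] = ratios[col]
    return ExpressionMatrix(data, expr.classes.copy(), expr.units, dict(expr.flags))
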