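"""Spot-table quantification: background, replicates, standard curves.

A raw spot table is reduced to calibrated per-sample amounts in four steps:
blank (BSA) spots give the assay background, replicate sample spots are
aggregated to a mean intensity and a percent CV (the technical-variance
statistic of the assay), a linear standard curve is fitted to the
serial-dilution series by ordinary least squares, and sample intensities
are interpolated on that curve into arbitrary units of expressed protein
per ng of total protein.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ExpressionMatrix, validate_spot_table

__all__ = [
    "StandardCurve",
    "QuantifiedSample",
    "blank_level",
    "aggregate_replicates",
    "fit_standard_curve",
    "calibrate",
    "quantify_table",
    "quantified_to_matrix",
]


@dataclass(frozen=True)
class StandardCurve:
    """Linear intensity-vs-concentration response of one antibody."""

    marker: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int

    @property
    def usable(self) -> bool:
        return self.slope > 0


@dataclass(frozen=True)
class QuantifiedSample:
    """Calibrated amount for one (sample, marker) pair."""

    sample_id: str
    marker: str
    class_label: str
    mean_intensity: float
    scv_percent: float  # NaN when undefined (single replicate / zero mean)
    amount: float
    flags: tuple[str, ...] = ()


def blank_level(table: pd.DataFrame, marker: str, *, fallback: float | None = None) -> float:
    """Mean intensity of the blank (BSA) spots for ``marker``.

    With no blank spots present, returns ``fallback`` if one was explicitly
    configured, otherwise raises.
    """
    validate_spot_table(table)
    blanks = table[(table["marker"] == marker) & (table["content_type"] == "blank")]
    if blanks.empty:
        if fallback is not None:
            return float(fallback)
        raise ValueError(f"marker {marker!r}: no blank spots and no fallback background")
    return float(blanks["intensity"].astype(float).mean())


def aggregate_replicates(intensities) -> tuple[float, float]:
    """Mean and percent CV (sample SD * 100 / |mean|) of replicate spots.

    The percent CV is NaN for a single replicate or an all-zero group,
    where it is undefined.
    """
    values = np.asarray(list(intensities), dtype=float)
    if values.size < 1:
        raise ValueError("at least one replicate intensity required")
    if np.any(values < 0):
        raise ValueError("intensities must be non-negative")
    mean = float(values.mean())
    if values.size < 2 or mean == 0.0:
        return mean, float("nan")
    sd = float(values.std(ddof=1))
    return mean, sd * 100.0 / abs(mean)


def fit_standard_curve(concentrations, intensities, marker: str) -> StandardCurve:
    """OLS fit of intensity on concentration (with intercept)."""
    x = np.asarray(list(concentrations), dtype=float)
    y = np.asarray(list(intensities), dtype=float)
    if x.size != y.size:
        raise ValueError("concentrations and intensities must align")
    if x.size < 3:
        raise ValueError(f"marker {marker!r}: need >= 3 standard points, got {x.size}")
    if np.unique(x).size < 2:
        raise ValueError(f"marker {marker!r}: all standard concentrations equal")
    result = sps.linregress(x, y)
    r_squared = float(result.rvalue**2) if not math.isnan(result.rvalue) else 0.0
    return StandardCurve(
        marker=marker,
        slope=float(result.slope),
        intercept=float(result.intercept),
        r_squared=r_squared,
        n_points=int(x.size),
    )


def calibrate(
    mean_intensity: float, curve: StandardCurve, background: float = 0.0
) -> tuple[float, tuple[str, ...]]:
    """Invert the standard curve: intensity -> amount.

    The 0-concentration standard already carries the background, so the
    curve intercept absorbs it and the inversion reduces to
    ``(mean_intensity - intercept) / slope``. Amounts below zero (signal
    under the blank level) clamp to 0 with a ``below_background`` flag.
    The ``background`` argument is kept for diagnostics on tables whose
    blank level differs from the fitted intercept; it cancels out of the
    inversion.
    """
    if not curve.usable:
        raise ValueError(
            f"marker {curve.marker!r}: standard curve unusable (slope {curve.slope})"
        )
    amount = (mean_intensity - curve.intercept) / curve.slope
    if amount < 0:
        return 0.0, ("below_background",)
    return float(amount), ()


def quantify_table(
    table: pd.DataFrame, *, blank_fallback: float | None = None
) -> tuple[list[QuantifiedSample], float]:
    """Full quantification of a spot table.

    Returns the per-(sample, marker) calibrated amounts and the array-level
    mean percent CV across all sample spot-groups (NaN for an empty table).
    """
    validate_spot_table(table)
    results: list[QuantifiedSample] = []
    scvs: list[float] = []
    for marker in pd.unique(table["marker"]):
        sub = table[table["marker"] == marker]
        standards = sub[sub["content_type"] == "standard"]
        samples = sub[sub["content_type"] == "sample"]
        if samples.empty:
            continue
        if standards.empty:
            raise ValueError(f"marker {marker!r}: no standard spots")
        background = blank_level(table, marker, fallback=blank_fallback)
        curve = fit_standard_curve(
            standards["nominal_concentration"].astype(float),
            standards["intensity"].astype(float),
            marker,
        )
        for sample_id, spots in samples.groupby("sample_id", sort=False):
            mean, scv = aggregate_replicates(spots["intensity"].astype(float))
            if not math.isnan(scv):
                scvs.append(scv)
            amount, flags = calibrate(mean, curve, background)
            results.append(
                QuantifiedSample(
                    sample_id=str(sample_id),
                    marker=str(marker),
                    class_label=str(spots["class_label"].iloc[0]),
                    mean_intensity=mean,
                    scv_percent=scv,
                    amount=amount,
                    flags=flags,
                )
            )
    mean_scv = float(np.mean(scvs)) if scvs else float("nan")
    return results, mean_scv


def quantified_to_matrix(results: list[QuantifiedSample]) -> ExpressionMatrix:
    """Pivot quantified samples into a calibrated ExpressionMatrix."""
    if not results:
        return ExpressionMatrix(
            pd.DataFrame(index=pd.Index([], name="sample_id")),
            pd.Series(dtype=object, index=pd.Index([], name="sample_id")),
            units="calibrated",
        )
    frame = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "marker": [r.marker for r in results],
            "amount": [r.amount for r in results],
            "class_label": [r.class_label for r in results],
        }
    )
    data = frame.pivot(index="sample_id", columns="marker", values="amount")
    # preserve first-seen order of samples and markers
    data = data.loc[
        pd.unique(frame["sample_id"]), pd.unique(frame["marker"])
    ]
    data.columns.name = None
    classes = frame.drop_duplicates("sample_id").set_index("sample_id")["class_label"]
    classes = classes.loc[data.index]
    classes.name = "class_label"
    return ExpressionMatrix(data, classes, units="calibrated")
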