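"""Synthetic cohorts and raw spot-intensity arrays.

Two generators make every downstream stage testable without real biopsies:

* :func:`simulate_cohort` draws per-sample marker expression (fold-of-control
  scale) from group-level mean +/- SEM summaries, using a moment-matched
  normal distribution truncated below at a floor (default 0, expression
  cannot be negative).  The parent (mu, sigma) are solved so that the
  truncated draws reproduce the requested mean exactly and the SEM-derived
  SD (SD = SEM * sqrt(n)) wherever a lower-truncated normal can attain that
  coefficient of variation; the few very dispersed cells where it cannot
  (CV >= 1) keep the exact mean with the SD capped at the attainable
  maximum and are flagged.

* :func:`simulate_spot_table` turns an expression matrix into a flat table
  of array spots: quadruplicate sample spots, a serial-dilution standard
  series (0-1 ug/ul), blank (BSA) spots, and multiplicative Gaussian
  technical noise with a configurable percent CV (default 8.6, the assay's
  replicate-spot coefficient of variation).
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import optimize
from scipy.stats import truncnorm

from .containers import SPOT_COLUMNS, ExpressionMatrix, validate_spot_table
from .panel import MarkerPanel, default_panel

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "ArrayLayoutSpec",
    "sem_to_sd",
    "simulate_cohort",
    "simulate_spot_table",
    "default_cohort_spec",
    "load_cohort_spec",
    "default_curve_params",
]

# Largest standardized truncation point used when a cell's target CV exceeds
# what a lower-truncated normal can reach (CV -> 1 as alpha -> +inf).
_ALPHA_CAP = 20.0


def sem_to_sd(sem: float, n: int) -> float:
    """Reconstruct the per-sample SD from a reported SEM: SD = SEM * sqrt(n)."""
    if n < 1:
        raise ValueError(f"group size must be >= 1, got {n}")
    if sem < 0:
        raise ValueError(f"SEM must be non-negative, got {sem}")
    return sem * math.sqrt(n)


@dataclass(frozen=True)
class GroupSpec:
    """One disease (or control) group: name, size, per-marker mean +/- SEM."""

    group_name: str
    n: int
    per_marker: dict[str, tuple[float, float]]
    control: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group {self.group_name!r}: n must be >= 1")
        for marker, (mean, sem) in self.per_marker.items():
            if mean < 0 or sem < 0:
                raise ValueError(
                    f"group {self.group_name!r}, marker {marker!r}: "
                    "mean and SEM must be non-negative"
                )


@dataclass(frozen=True)
class CohortSpec:
    """Simulation configuration: the groups, the seed, and the value floor."""

    groups: tuple[GroupSpec, ...]
    seed: int = 0
    value_floor: float = 0.0

    def __post_init__(self) -> None:
        names = [g.group_name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")
        n_control = sum(g.control for g in self.groups)
        if n_control != 1:
            raise ValueError(f"exactly one control group required, found {n_control}")
        if self.value_floor < 0:
            raise ValueError("value_floor must be non-negative")

    @property
    def control_label(self) -> str:
        return next(g.group_name for g in self.groups if g.control)

    def subset(self, group_names: list[str], seed: int | None = None) -> "CohortSpec":
        """Restrict to the named groups (control must be among them)."""
        keep = [g for g in self.groups if g.group_name in group_names]
        missing = set(group_names) - {g.group_name for g in keep}
        if missing:
            raise KeyError(f"unknown groups: {sorted(missing)}")
        return CohortSpec(
            tuple(keep), self.seed if seed is None else seed, self.value_floor
        )

    def with_seed(self, seed: int) -> "CohortSpec":
        return CohortSpec(self.groups, seed, self.value_floor)


@dataclass(frozen=True)
class ArrayLayoutSpec:
    """Array geometry and technical-noise settings for spot simulation."""

    replicates_per_sample: int = 4
    standard_concentrations: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    n_blank_spots: int = 4
    technical_cv_percent: float = 8.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_sample < 1:
            raise ValueError("replicates_per_sample must be >= 1")
        concs = self.standard_concentrations
        if len(concs) < 2 or min(concs) != 0.0:
            raise ValueError("standard series must contain 0 and its maximum")
        if any(c < 0 for c in concs):
            raise ValueError("standard concentrations must be non-negative")
        if self.technical_cv_percent < 0:
            raise ValueError("technical_cv_percent must be non-negative")
        if self.n_blank_spots < 0:
            raise ValueError("n_blank_spots must be non-negative")


def _truncated_cv(alpha: float) -> float:
    """CV of a standard normal truncated to [alpha, inf), about its offset mean.

    For parent N(mu, sigma) truncated at floor f with alpha = (f - mu)/sigma,
    this equals SD(X) / (E[X] - f), which is scale- and location-free.
    """
    mean, var = truncnorm.stats(alpha, np.inf, moments="mv")
    return float(np.sqrt(var) / (mean - alpha))


@functools.lru_cache(maxsize=4096)
def _match_truncated_normal(
    mean: float, sd: float, floor: float
) -> tuple[float, float, bool]:
    """Parent (mu, sigma) whose floor-truncated law has the target moments.

    Returns (mu, sigma, sd_capped). If the target CV about the floor is not
    attainable (a lower-truncated normal cannot exceed CV ~1) the mean is
    matched exactly with the truncation point capped and ``sd_capped`` True.
    """
    if mean < floor:
        raise ValueError(f"target mean {mean} below floor {floor}")
    excess = mean - floor
    if sd == 0 or excess == 0:
        # Degenerate: constant at the mean (sd > 0 with mean at the floor is
        # unattainable for any truncated normal; collapse to the mean).
        return mean, 0.0, sd > 0
    target_cv = sd / excess
    cap_cv = _truncated_cv(_ALPHA_CAP)
    if target_cv >= cap_cv:
        alpha = _ALPHA_CAP
        capped = True
    else:
        alpha = optimize.brentq(
            lambda a: _truncated_cv(a) - target_cv, -39.0, _ALPHA_CAP, xtol=1e-12
        )
        capped = False
    mz, vz = truncnorm.stats(alpha, np.inf, moments="mv")
    sigma = excess / float(mz - alpha)
    mu = floor - alpha * sigma
    return mu, sigma, capped


def _draw_truncated(
    mean: float, sd: float, floor: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    mu, sigma, _ = _match_truncated_normal(mean, sd, floor)
    if sigma == 0.0:
        return np.full(size, mean, dtype=float)
    alpha = (floor - mu) / sigma
    return truncnorm.rvs(
        alpha, np.inf, loc=mu, scale=sigma, size=size, random_state=rng
    )


def simulate_cohort(
    spec: CohortSpec, panel: MarkerPanel | None = None
) -> ExpressionMatrix:
    """Draw a synthetic cohort with the group structure of ``spec``.

    For each group g and column m, draws ``n_g`` values from the
    moment-matched truncated normal with mean ``mean_fold`` and
    SD ``sem * sqrt(n_g)``. Ratio columns present in the group summaries
    are drawn directly like markers. Reproducible under a fixed seed.
    """
    panel = panel or default_panel()
    columns = panel.all_columns
    for group in spec.groups:
        missing = [m for m in columns if m not in group.per_marker]
        if missing:
            raise KeyError(
                f"group {group.group_name!r} lacks summaries for markers {missing}"
            )
    rng = np.random.default_rng(spec.seed)
    rows: list[np.ndarray] = []
    sample_ids: list[str] = []
    labels: list[str] = []
    capped: list[tuple[str, str]] = []
    for group in spec.groups:
        block = np.empty((group.n, len(columns)), dtype=float)
        for j, marker in enumerate(columns):
            mean, sem = group.per_marker[marker]
            sd = sem_to_sd(sem, group.n)
            block[:, j] = _draw_truncated(mean, sd, spec.value_floor, group.n, rng)
            if sd > 0 and _match_truncated_normal(mean, sd, spec.value_floor)[2]:
                capped.append((group.group_name, marker))
        rows.append(block)
        sample_ids.extend(f"{group.group_name}_{i + 1:02d}" for i in range(group.n))
        labels.extend([group.group_name] * group.n)
    data = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, len(columns))),
        index=pd.Index(sample_ids, name="sample_id"),
        columns=columns,
    )
    classes = pd.Series(labels, index=data.index, name="class_label")
    flags = {"sd_capped_cells": capped} if capped else {}
    return ExpressionMatrix(data, classes, units="fold_of_control", flags=flags)


def default_curve_params(
    markers: list[str], slope: float = 1000.0, intercept: float = 50.0
) -> dict[str, tuple[float, float]]:
    """Identical linear response (slope, intercept) for every marker."""
    return {m: (slope, intercept) for m in markers}


def simulate_spot_table(
    expr: ExpressionMatrix,
    layout: ArrayLayoutSpec,
    curve_params: dict[str, tuple[float, float]],
) -> pd.DataFrame:
    """Emit raw array spots for every marker of ``expr``.

    Per marker: one spot per standard concentration (expected intensity
    ``slope * conc + intercept``), ``n_blank_spots`` blanks at the intercept
    level, and ``replicates_per_sample`` spots per sample at
    ``slope * expression + intercept``. Every spot is perturbed by
    multiplicative Gaussian noise with the layout's percent CV and floored
    at zero intensity.
    """
    for marker in expr.markers:
        if marker not in curve_params:
            raise KeyError(f"no curve parameters for marker {marker!r}")
        slope, _ = curve_params[marker]
        if slope <= 0:
            raise ValueError(f"marker {marker!r}: slope must be positive")
    rng = np.random.default_rng(layout.seed)
    cv = layout.technical_cv_percent / 100.0
    records: list[tuple] = []

    def noisy(expected: float) -> float:
        value = expected * (1.0 + cv * rng.standard_normal()) if cv > 0 else expected
        return max(value, 0.0)

    for marker in expr.markers:
        slope, intercept = curve_params[marker]
        for conc in layout.standard_concentrations:
            records.append(
                (marker, "standard", "", "", 1, conc, noisy(slope * conc + intercept))
            )
        for b in range(layout.n_blank_spots):
            records.append((marker, "blank", "", "", b + 1, np.nan, noisy(intercept)))
        for sample_id, value in expr.data[marker].items():
            label = expr.classes.loc[sample_id]
            for r in range(layout.replicates_per_sample):
                records.append(
                    (
                        marker,
                        "sample",
                        sample_id,
                        label,
                        r + 1,
                        np.nan,
                        noisy(slope * value + intercept),
                    )
                )
    table = pd.DataFrame(records, columns=list(SPOT_COLUMNS))
    return validate_spot_table(table)


def load_cohort_spec(source) -> CohortSpec:
    """Build a :class:`CohortSpec` from a YAML path or a parsed mapping."""
    if isinstance(source, dict):
        config = source
    else:  # str / pathlib.Path
        with open(source, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    groups = []
    for name, entry in config["groups"].items():
        markers = {m: (float(v[0]), float(v[1])) for m, v in entry["markers"].items()}
        groups.append(
            GroupSpec(
                group_name=name,
                n=int(entry["n"]),
                per_marker=markers,
                control=bool(entry.get("control", False)),
            )
        )
    return CohortSpec(
        tuple(groups),
        seed=int(config.get("seed", 0)),
        value_floor=float(config.get("value_floor", 0.0)),
    )


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The packaged nine-group cohort summary (73 biopsies)."""
    ref = resources.files("myoarray.data").joinpath("default_cohort.yaml")
    with ref.open("r") as fh:
        spec = load_cohort_spec(yaml.safe_load(fh))
    return spec.with_seed(seed)
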