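"""Inferential layer: pooled two-tailed t, one-way ANOVA, Dunnett post hoc.

Dunnett's many-to-one comparisons against the control are computed with a
Monte-Carlo integration of the null distribution of max|T| over the
correlated multivariate-t family (correlation rho_ij =
sqrt(n_i n_j / ((n_i + n0)(n_j + n0)))), which stays exact under the
unbalanced group sizes of real cohorts where tabulated critical values do
not apply. Significance tiers follow the conventional 0.05 / 0.001 cuts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ExpressionMatrix

__all__ = [
    "StatResult",
    "student_t_two_tailed",
    "anova_oneway",
    "dunnett_many_to_one",
    "stats_table",
]

TIER_NS = "ns"
TIER_05 = "p<0.05"
TIER_001 = "p<0.001"


def significance_tier(p: float) -> str:
    if p < 0.001:
        return TIER_001
    if p < 0.05:
        return TIER_05
    return TIER_NS


@dataclass(frozen=True)
class StatResult:
    """One comparison of a treatment group against the control."""

    marker: str
    comparison: str
    t_statistic: float
    df: float
    p_value: float
    p_adjusted: float
    tier: str
    flags: tuple[str, ...] = ()


def _as_array(values, name: str, min_size: int = 2) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    if arr.size < min_size:
        raise ValueError(f"{name}: need >= {min_size} values, got {arr.size}")
    return arr


def student_t_two_tailed(
    x, y, *, marker: str = "", comparison: str = ""
) -> StatResult:
    """Pooled-variance two-tailed Student's t-test."""
    xa = _as_array(x, "x")
    ya = _as_array(y, "y")
    nx, ny = xa.size, ya.size
    df = nx + ny - 2
    pooled_var = (
        (nx - 1) * xa.var(ddof=1) + (ny - 1) * ya.var(ddof=1)
    ) / df
    diff = xa.mean() - ya.mean()
    flags: tuple[str, ...] = ()
    if pooled_var == 0.0:
        if diff == 0.0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat = np.inf if diff > 0 else -np.inf
            p = 0.0
            flags = ("degenerate_zero_variance",)
    else:
        se = np.sqrt(pooled_var * (1.0 / nx + 1.0 / ny))
        t_stat = diff / se
        p = 2.0 * sps.t.sf(abs(t_stat), df)
    return StatResult(
        marker=marker,
        comparison=comparison,
        t_statistic=float(t_stat),
        df=float(df),
        p_value=float(p),
        p_adjusted=float(p),
        tier=significance_tier(p),
        flags=flags,
    )


def anova_oneway(groups) -> tuple[float, int, int, float]:
    """One-way fixed-effects ANOVA: (F, df_between, df_within, p)."""
    arrays = [_as_array(g, f"group {i}") for i, g in enumerate(groups)]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    df1, df2 = k - 1, n_total - k
    if all(np.array_equal(a, arrays[0]) for a in arrays[1:]) and all(
        a.var() == 0 for a in arrays
    ):
        return 0.0, df1, df2, 1.0
    f_stat, p = sps.f_oneway(*arrays)
    if np.isnan(f_stat):  # zero within- and between-group variance
        return 0.0, df1, df2, 1.0
    return float(f_stat), df1, df2, float(p)


def _dunnett_null_max_t(
    treatment_sizes: np.ndarray,
    n_control: int,
    df: int,
    mc_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Monte-Carlo sample of max|T| under the Dunnett null.

    T = Z / sqrt(W/df) with Z multivariate normal with the many-to-one
    correlation structure and W an independent chi-square(df), shared by
    all coordinates (one pooled variance estimate).
    """
    lam = np.sqrt(treatment_sizes / (treatment_sizes + n_control))
    # Z_i = lam_i * Z0 + sqrt(1 - lam_i^2) * E_i gives corr(Z_i, Z_j) = lam_i lam_j
    z0 = rng.standard_normal(mc_draws)[:, None]
    eps = rng.standard_normal((mc_draws, lam.size))
    z = lam * z0 + np.sqrt(1.0 - lam**2) * eps
    w = rng.chisquare(df, size=mc_draws)[:, None] / df
    t = z / np.sqrt(w)
    return np.abs(t).max(axis=1)


def dunnett_many_to_one(
    groups,
    control,
    *,
    mc_draws: int = 100_000,
    seed: int = 0,
    marker: str = "",
    group_names: list[str] | None = None,
) -> list[StatResult]:
    """Many-to-one comparisons of each group against the control.

    Per-group t statistics use the variance pooled across all groups
    (including the control); the adjusted p-value of each comparison is the
    Monte-Carlo tail probability of the null max|T| beyond the observed
    |t|.
    """
    if mc_draws < 1_000:
        warnings.warn(
            f"mc_draws={mc_draws} gives an unstable Dunnett adjustment",
            stacklevel=2,
        )
    arrays = [_as_array(g, f"group {i}") for i, g in enumerate(groups)]
    if not arrays:
        raise ValueError("need at least one treatment group")
    ctrl = _as_array(control, "control")
    names = group_names or [f"group{i + 1}" for i in range(len(arrays))]
    if len(names) != len(arrays):
        raise ValueError("group_names must align with groups")
    all_arrays = arrays + [ctrl]
    n_total = sum(a.size for a in all_arrays)
    df = n_total - len(all_arrays)
    if df < 1:
        raise ValueError("pooled residual degrees of freedom must be >= 1")
    pooled_var = sum((a.size - 1) * a.var(ddof=1) for a in all_arrays) / df

    sizes = np.array([a.size for a in arrays], dtype=float)
    rng = np.random.default_rng(seed)
    null_max_t = _dunnett_null_max_t(sizes, ctrl.size, df, mc_draws, rng)

    results = []
    for name, arr in zip(names, arrays):
        diff = arr.mean() - ctrl.mean()
        flags: tuple[str, ...] = ()
        if pooled_var == 0.0:
            if diff == 0.0:
                t_stat, p_raw, p_adj = 0.0, 1.0, 1.0
            else:
                t_stat = np.inf if diff > 0 else -np.inf
                p_raw = p_adj = 0.0
                flags = ("degenerate_zero_variance",)
        else:
            se = np.sqrt(pooled_var * (1.0 / arr.size + 1.0 / ctrl.size))
            t_stat = diff / se
            p_raw = 2.0 * sps.t.sf(abs(t_stat), df)
            p_adj = float(np.mean(null_max_t >= abs(t_stat)))
            p_adj = max(p_adj, p_raw)  # guard MC undershoot of the raw p
        results.append(
            StatResult(
                marker=marker,
                comparison=f"{name} vs control",
                t_statistic=float(t_stat),
                df=float(df),
                p_value=float(p_raw),
                p_adjusted=float(p_adj),
                tier=significance_tier(p_adj),
                flags=flags,
            )
        )
    return results


def stats_table(
    expr: ExpressionMatrix,
    control_label: str,
    *,
    method: str = "dunnett",
    mc_draws: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Marker x group comparison table against the control group.

    ``method`` is ``"dunnett"`` (ANOVA-style pooled variance with
    familywise adjustment) or ``"ttest"`` (plain pairwise pooled t).
    """
    if method not in ("dunnett", "ttest"):
        raise ValueError(f"unknown method {method!r}")
    labels = [lab for lab in pd.unique(expr.classes) if lab != control_label]
    if control_label not in set(expr.classes):
        raise ValueError(f"control label {control_label!r} not in matrix")
    rows = []
    for j, marker in enumerate(expr.markers):
        ctrl = expr.group_values(control_label)[marker].to_numpy()
        groups = [expr.group_values(lab)[marker].to_numpy() for lab in labels]
        if method == "dunnett":
            results = dunnett_many_to_one(
                groups,
                ctrl,
                mc_draws=mc_draws,
                seed=seed + j,
                marker=marker,
                group_names=labels,
            )
        else:
            results = [
                student_t_two_tailed(
                    g, ctrl, marker=marker, comparison=f"{lab} vs control"
                )
                for lab, g in zip(labels, groups)
            ]
        rows.extend(results)
    return pd.DataFrame(
        {
            "marker": [r.marker for r in rows],
            "comparison": [r.comparison for r in rows],
            "t_statistic": [r.t_statistic for r in rows],
            "df": [r.df for r in rows],
            "p_value": [r.p_value for r in rows],
            "p_adjusted": [r.p_adjusted for r in rows],
            "tier": [r.tier for r in rows],
        }
    )
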