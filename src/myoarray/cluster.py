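"""Agglomerative Euclidean/WPGMA clustering and classification metrics.

The linkage is written out explicitly rather than delegated, because the
update rule is the method under study: on each step the closest pair of
clusters merges, and the distance from the merged cluster (a u b) to any
other cluster c is the size-independent average (d(a,c) + d(b,c)) / 2
(WPGMA, "weighted group average"). The size-weighted UPGMA update is
available as an option. Ties are broken deterministically by the smallest
(cluster-id ordered) pair. Cutting the tree at k clusters undoes the last
k-1 merges; clusters map to classes by majority vote, from which per-class
sensitivity and control specificity are derived.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = [
    "DistanceMatrix",
    "Linkage",
    "ClusterPerformance",
    "euclidean_distances",
    "wpgma_linkage",
    "cut_tree",
    "cluster_performance",
    "linkage_to_newick",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class Merge:
    """One agglomeration step (scipy-style cluster ids: leaves are 0..n-1)."""

    left: int
    right: int
    height: float
    size: int


@dataclass(frozen=True)
class Linkage:
    """Ordered merge records for n leaves (exactly n-1 merges)."""

    leaf_ids: tuple[str, ...]
    merges: tuple[Merge, ...]
    monotone: bool = True

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)


@dataclass(frozen=True)
class ClusterPerformance:
    """Majority-vote classification quality of a flat clustering."""

    cluster_to_class: dict[int, str]
    sensitivity_percent: dict[str, float]  # recall: % of class c in c-mapped clusters
    precision_percent: dict[str, float]  # % of samples in c-mapped clusters that are c
    specificity_percent: float  # % of controls in control-mapped clusters
    pooled_pathologic_sensitivity: float
    pooled_control_specificity: float


def euclidean_distances(
    expr: ExpressionMatrix, markers: list[str] | None = None
) -> DistanceMatrix:
    """Pairwise Euclidean distances over the selected marker columns."""
    sub = expr.subset_markers(markers) if markers is not None else expr
    values = sub.data.to_numpy(dtype=float)
    if np.isnan(values).any():
        bad = sub.data.index[sub.data.isna().any(axis=1)].tolist()
        raise ValueError(f"missing values in samples: {bad}")
    diff = values[:, None, :] - values[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against float noise
    return DistanceMatrix(tuple(sub.data.index), d)


def wpgma_linkage(dist: DistanceMatrix, *, method: str = "wpgma") -> Linkage:
    """Agglomerative linkage under the WPGMA (default) or UPGMA update."""
    if method not in ("wpgma", "upgma"):
        raise ValueError(f"unknown linkage method {method!r}")
    n = dist.n
    if n < 2:
        raise ValueError("need at least two leaves")
    # active cluster id -> index into the working distance dict
    d: dict[tuple[int, int], float] = {}
    active: list[int] = list(range(n))
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = float(dist.values[i, j])

    def get(a: int, b: int) -> float:
        return d[(a, b) if a < b else (b, a)]

    merges: list[Merge] = []
    next_id = n
    monotone = True
    last_height = -np.inf
    for _ in range(n - 1):
        # closest pair; ties -> smallest (a, b) with a < b by cluster id
        best = None
        best_d = np.inf
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                dd = get(a, b)
                if dd < best_d or (dd == best_d and best is not None and (a, b) < best):
                    best_d = dd
                    best = (a, b)
        a, b = best  # type: ignore[misc]
        if best_d < last_height - 1e-12:
            monotone = False
        last_height = max(last_height, best_d)
        new_size = sizes[a] + sizes[b]
        for c in active:
            if c in (a, b):
                continue
            if method == "wpgma":
                dc = (get(a, c) + get(b, c)) / 2.0
            else:  # upgma: size-weighted average
                dc = (sizes[a] * get(a, c) + sizes[b] * get(b, c)) / new_size
            d[(min(c, next_id), max(c, next_id))] = dc
        active = [c for c in active if c not in (a, b)] + [next_id]
        sizes[next_id] = new_size
        merges.append(Merge(a, b, float(best_d), new_size))
        next_id += 1
    return Linkage(dist.ids, tuple(merges), monotone=monotone)


def _members(linkage: Linkage) -> dict[int, list[int]]:
    """Cluster id -> leaf indices, for every cluster ever formed."""
    members: dict[int, list[int]] = {i: [i] for i in range(linkage.n_leaves)}
    for step, merge in enumerate(linkage.merges):
        members[linkage.n_leaves + step] = members[merge.left] + members[merge.right]
    return members


def cut_tree(linkage: Linkage, k: int) -> np.ndarray:
    """Labels of the k-cluster cut (cluster label = smallest member index)."""
    n = linkage.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    members = _members(linkage)
    # apply the first n - k merges
    active = set(range(n))
    for step in range(n - k):
        merge = linkage.merges[step]
        active.discard(merge.left)
        active.discard(merge.right)
        active.add(n + step)
    labels = np.empty(n, dtype=int)
    for cid in active:
        leaves = members[cid]
        labels[leaves] = min(leaves)
    return labels


def _majority_map(
    labels: np.ndarray, truth: pd.Series
) -> dict[int, str]:
    """Cluster -> majority true class; ties to the larger cohort, then name."""
    counts = truth.value_counts()
    mapping: dict[int, str] = {}
    for cid in np.unique(labels):
        in_cluster = truth[labels == cid]
        tally = in_cluster.value_counts()
        top = tally.max()
        candidates = sorted(
            tally.index[tally == top], key=lambda c: (-counts[c], c)
        )
        mapping[int(cid)] = candidates[0]
    return mapping


def cluster_performance(
    labels, truth, control_label: str
) -> ClusterPerformance:
    """Sensitivity / specificity of a flat clustering against known classes.

    Each cluster is assigned its majority true class. Per-class sensitivity
    (recall) is the percentage of that class's samples landing in clusters
    mapped to it; the precision-style variant (share of the mapped
    clusters' samples that belong to the class) is reported alongside.
    Specificity is the percentage of control samples in control-mapped
    clusters. Pooled figures treat all non-control classes as one
    pathologic class, re-deriving the majority map on the binarized labels.
    """
    labels = np.asarray(labels)
    truth = pd.Series(list(truth))
    if labels.shape[0] != len(truth):
        raise ValueError("labels and truth must have the same length")

    mapping = _majority_map(labels, truth)
    mapped = pd.Series([mapping[int(c)] for c in labels], index=truth.index)

    sensitivity: dict[str, float] = {}
    precision: dict[str, float] = {}
    for cls in sorted(truth.unique()):
        is_cls = truth == cls
        in_mapped = mapped == cls
        sensitivity[cls] = 100.0 * float((is_cls & in_mapped).sum()) / float(is_cls.sum())
        called = float(in_mapped.sum())
        precision[cls] = (
            100.0 * float((is_cls & in_mapped).sum()) / called if called else float("nan")
        )
    specificity = sensitivity.get(control_label, float("nan"))

    # pooled: binarize to control vs pathologic, remap by majority
    binary = truth.where(truth == control_label, "pathologic")
    bin_map = _majority_map(labels, binary)
    bin_mapped = pd.Series([bin_map[int(c)] for c in labels], index=truth.index)
    is_path = binary == "pathologic"
    pooled_sens = (
        100.0
        * float((is_path & (bin_mapped == "pathologic")).sum())
        / float(is_path.sum())
        if is_path.any()
        else float("nan")
    )
    is_ctrl = binary == control_label
    pooled_spec = (
        100.0
        * float((is_ctrl & (bin_mapped == control_label)).sum())
        / float(is_ctrl.sum())
        if is_ctrl.any()
        else float("nan")
    )
    return ClusterPerformance(
        cluster_to_class=mapping,
        sensitivity_percent=sensitivity,
        precision_percent=precision,
        specificity_percent=specificity,
        pooled_pathologic_sensitivity=pooled_sens,
        pooled_control_specificity=pooled_spec,
    )


def linkage_to_newick(linkage: Linkage) -> str:
    """Newick string with ultrametric branch lengths (leaf depth = height/2)."""
    n = linkage.n_leaves
    depth: dict[int, float] = {i: 0.0 for i in range(n)}
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    node: dict[int, str] = {i: linkage.leaf_ids[i] for i in range(n)}
    for step, merge in enumerate(linkage.merges):
        h = merge.height / 2.0
        # larger subtree first, ties by cluster id, for a stable layout
        a, b = sorted((merge.left, merge.right), key=lambda c: (-sizes[c], c))
        parts = (f"{node[a]}:{h - depth[a]:g}", f"{node[b]}:{h - depth[b]:g}")
        cid = n + step
        node[cid] = f"({parts[0]},{parts[1]})"
        depth[cid] = h
        sizes[cid] = sizes[merge.left] + sizes[merge.right]
    return node[n + len(linkage.merges) - 1] + ";"
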