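"""WPGMA linkage, tree cutting, majority-vote performance, Newick export."""

import numpy as np
import pytest
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist

from myoarray import (
    DistanceMatrix,
    cluster_performance,
    cut_tree,
    euclidean_distances,
    linkage_to_newick,
    wpgma_linkage,
)

from conftest import make_matrix


def three_leaf_distance():
    # d(A,B) = 2, d(A,C) = 4, d(B,C) = 6
    values = np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 6.0], [4.0, 6.0, 0.0]])
    return DistanceMatrix(("A", "B", "C"), values)


class TestDistanceMatrix:
    def test_euclidean_distances_match_scipy(self):
        rng = np.random.default_rng(1)
        values = rng.normal(0, 1, (6, 3))
        expr = make_matrix(values, [f"s{i}" for i in range(6)], ["X"] * 6,
                           ["a", "b", "c"], units="log2_relative")
        dist = euclidean_distances(expr)
        from scipy.spatial.distance import squareform

        assert np.allclose(dist.values, squareform(pdist(values)))

    def test_missing_values_rejected_with_sample_names(self):
        values = [[0.0, 1.0], [np.nan, 2.0]]
        expr = make_matrix(values, ["s0", "s1"], ["X", "X"], ["a", "b"],
                           units="log2_relative")
        with pytest.raises(ValueError, match="s1"):
            euclidean_distances(expr)

    def test_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(("a", "b"), np.array([[1.0, 2.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="non-negative"):
            DistanceMatrix(("a", "b"), np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestWpgmaLinkage:
    def test_hand_executed_three_leaf_example(self):
        linkage = wpgma_linkage(three_leaf_distance())
        first, second = linkage.merges
        # A and B merge at height 2; the merged cluster's distance to C is
        # (4 + 6) / 2 = 5 under the WPGMA update.
        assert (first.left, first.right, first.height) == (0, 1, 2.0)
        assert second.height == pytest.approx(5.0)
        assert linkage.monotone

    def test_upgma_update_weights_by_size(self):
        # four leaves arranged so WPGMA and UPGMA disagree on the last height
        values = np.array(
            [
                [0.0, 1.0, 8.0, 9.0],
                [1.0, 0.0, 9.0, 12.0],
                [8.0, 9.0, 0.0, 2.0],
                [9.0, 12.0, 2.0, 0.0],
            ]
        )
        dist = DistanceMatrix(("a", "b", "c", "d"), values)
        w = wpgma_linkage(dist, method="wpgma").merges[-1].height
        u = wpgma_linkage(dist, method="upgma").merges[-1].height
        assert w == pytest.approx((8.5 + 10.5) / 2)  # simple average
        assert u == pytest.approx((8 + 9 + 9 + 12) / 4)  # leaf-count average

    def test_matches_scipy_weighted_linkage_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(3, 9))
            points = rng.normal(0, 1, (n, 3))
            dist = DistanceMatrix(
                tuple(f"s{i}" for i in range(n)),
                np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1)),
            )
            ours = wpgma_linkage(dist)
            ref = sch.linkage(pdist(points), method="weighted")
            assert np.allclose([m.height for m in ours.merges], ref[:, 2])

    def test_unknown_method_and_tiny_input_rejected(self):
        with pytest.raises(ValueError, match="method"):
            wpgma_linkage(three_leaf_distance(), method="single")
        with pytest.raises(ValueError, match="two leaves"):
            wpgma_linkage(DistanceMatrix(("a",), np.zeros((1, 1))))


class TestCutTree:
    def test_three_leaf_cuts(self):
        linkage = wpgma_linkage(three_leaf_distance())
        assert cut_tree(linkage, 1).tolist() == [0, 0, 0]
        assert cut_tree(linkage, 2).tolist() == [0, 0, 2]  # {A,B} vs {C}
        assert cut_tree(linkage, 3).tolist() == [0, 1, 2]

    def test_cuts_are_nested(self):
        rng = np.random.default_rng(3)
        points = rng.normal(0, 1, (10, 2))
        expr = make_matrix(points, [f"s{i}" for i in range(10)], ["X"] * 10,
                           ["a", "b"], units="log2_relative")
        linkage = wpgma_linkage(euclidean_distances(expr))
        for k in range(1, 10):
            coarse = cut_tree(linkage, k)
            fine = cut_tree(linkage, k + 1)
            # every fine cluster lies entirely inside one coarse cluster
            for fid in np.unique(fine):
                assert len(np.unique(coarse[fine == fid])) == 1

    def test_invalid_k_rejected(self):
        linkage = wpgma_linkage(three_leaf_distance())
        with pytest.raises(ValueError):
            cut_tree(linkage, 0)
        with pytest.raises(ValueError):
            cut_tree(linkage, 4)


class TestClusterPerformance:
    def test_perfect_clustering_scores_100(self):
        labels = [0, 0, 1, 1]
        truth = ["CTR", "CTR", "DIS", "DIS"]
        perf = cluster_performance(labels, truth, "CTR")
        assert perf.sensitivity_percent == {"CTR": 100.0, "DIS": 100.0}
        assert perf.precision_percent == {"CTR": 100.0, "DIS": 100.0}
        assert perf.specificity_percent == 100.0
        assert perf.pooled_pathologic_sensitivity == 100.0
        assert perf.pooled_control_specificity == 100.0

    def test_majority_mapping_and_partial_scores(self):
        # cluster 0: 3 CTR + 1 DIS -> CTR; cluster 1: 2 DIS -> DIS
        labels = [0, 0, 0, 0, 1, 1]
        truth = ["CTR", "CTR", "CTR", "DIS", "DIS", "DIS"]
        perf = cluster_performance(labels, truth, "CTR")
        assert perf.cluster_to_class == {0: "CTR", 1: "DIS"}
        assert perf.sensitivity_percent["DIS"] == pytest.approx(200 / 3)
        assert perf.specificity_percent == 100.0
        assert perf.precision_percent["CTR"] == pytest.approx(75.0)

    def test_tie_breaks_to_larger_cohort(self):
        # cluster holds 1 CTR + 1 DIS; DIS cohort is larger overall
        labels = [0, 0, 1, 1, 1]
        truth = ["CTR", "DIS", "DIS", "DIS", "CTR"]
        perf = cluster_performance(labels, truth, "CTR")
        assert perf.cluster_to_class[0] == "DIS"

    def test_class_without_mapped_cluster_has_nan_precision(self):
        labels = [0, 0, 0]
        truth = ["CTR", "CTR", "DIS"]
        perf = cluster_performance(labels, truth, "CTR")
        assert perf.sensitivity_percent["DIS"] == 0.0
        assert np.isnan(perf.precision_percent["DIS"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cluster_performance([0, 1], ["CTR"], "CTR")


class TestNewick:
    def test_three_leaf_ultrametric_newick(self):
        linkage = wpgma_linkage(three_leaf_distance())
        assert linkage_to_newick(linkage) == "((A:1,B:1):1.5,C:2.5);"

    def test_leaf_depths_are_half_merge_height(self):
        # root at height 5 -> every leaf sits at depth 2.5 from the root
        linkage = wpgma_linkage(three_leaf_distance())
        newick = linkage_to_newick(linkage)
        # A path: 1 + 1.5 = 2.5; C path: 2.5
        assert "C:2.5" in newick and "A:1," in newick
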