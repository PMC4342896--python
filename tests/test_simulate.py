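"""Cohort and spot-table generators: moments, determinism, validation."""

import math

import numpy as np
import pytest

from myoarray import (
    ArrayLayoutSpec,
    CohortSpec,
    GroupSpec,
    default_cohort_spec,
    default_curve_params,
    load_cohort_spec,
    sem_to_sd,
    simulate_cohort,
    simulate_spot_table,
)
from myoarray.simulate import _match_truncated_normal


class TestSemToSd:
    def test_reported_sem_scales_back_by_sqrt_n(self):
        assert sem_to_sd(0.1, 20) == pytest.approx(0.4472135954999579)
        assert sem_to_sd(0.6, 6) == pytest.approx(1.4696938456699067)

    def test_zero_sem_gives_zero_sd(self):
        assert sem_to_sd(0.0, 12) == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sem_to_sd(0.1, 0)
        with pytest.raises(ValueError):
            sem_to_sd(-0.1, 5)


class TestMomentMatching:
    def test_matched_parent_reproduces_mean_and_sd_exactly(self):
        from scipy.stats import truncnorm

        mu, sigma, capped = _match_truncated_normal(1.0, 0.4472, 0.0)
        assert not capped
        a = (0.0 - mu) / sigma
        m, v = truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        assert m == pytest.approx(1.0, abs=1e-9)
        assert math.sqrt(v) == pytest.approx(0.4472, abs=1e-9)

    def test_dispersed_cell_keeps_exact_mean_with_capped_sd(self):
        # CV about the floor >= 1 is unattainable for a lower-truncated
        # normal; the mean must still be matched exactly.
        from scipy.stats import truncnorm

        mean, sd = 0.2, 0.6
        mu, sigma, capped = _match_truncated_normal(mean, sd, 0.0)
        assert capped
        a = (0.0 - mu) / sigma
        m, v = truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        assert m == pytest.approx(mean, abs=1e-9)
        assert math.sqrt(v) < sd

    def test_zero_sd_collapses_to_constant(self):
        mu, sigma, capped = _match_truncated_normal(0.7, 0.0, 0.0)
        assert (mu, sigma, capped) == (0.7, 0.0, False)


class TestSimulateCohort:
    def test_sample_counts_labels_and_ids(self, small_cohort_spec, two_marker_panel):
        expr = simulate_cohort(small_cohort_spec, two_marker_panel)
        assert len(expr.sample_ids) == 9
        assert expr.sample_ids[0] == "CTR_01"
        assert expr.sample_ids[-1] == "DIS_04"
        assert list(expr.classes.unique()) == ["CTR", "DIS"]
        assert expr.units == "fold_of_control"

    def test_same_seed_is_bit_identical(self, small_cohort_spec, two_marker_panel):
        a = simulate_cohort(small_cohort_spec, two_marker_panel)
        b = simulate_cohort(small_cohort_spec, two_marker_panel)
        assert a.data.equals(b.data)

    def test_different_seeds_differ(self, small_cohort_spec, two_marker_panel):
        a = simulate_cohort(small_cohort_spec, two_marker_panel)
        b = simulate_cohort(small_cohort_spec.with_seed(8), two_marker_panel)
        assert not a.data.equals(b.data)

    def test_values_respect_floor(self, two_marker_panel):
        spec = CohortSpec(
            (GroupSpec("CTR", 200, {"M1": (0.3, 0.2), "M2": (0.2, 0.245)},
                       control=True),),
            seed=3,
        )
        expr = simulate_cohort(spec, two_marker_panel)
        assert (expr.data.to_numpy() >= 0.0).all()

    def test_zero_sem_group_is_constant(self, two_marker_panel):
        spec = CohortSpec(
            (GroupSpec("CTR", 6, {"M1": (0.0, 0.0), "M2": (1.0, 0.0)},
                       control=True),),
            seed=1,
        )
        expr = simulate_cohort(spec, two_marker_panel)
        assert (expr.data["M1"] == 0.0).all()
        assert (expr.data["M2"] == 1.0).all()

    def test_capped_cells_are_flagged(self, two_marker_panel):
        spec = CohortSpec(
            (GroupSpec("CTR", 6, {"M1": (0.2, 0.1), "M2": (1.0, 0.1)},
                       control=True),),
            seed=1,
        )
        expr = simulate_cohort(spec, two_marker_panel)
        # SD = 0.1 * sqrt(6) = 0.245 > attainable for mean 0.2 above floor 0
        assert ("CTR", "M1") in expr.flags["sd_capped_cells"]

    def test_missing_marker_summary_raises(self, two_marker_panel):
        spec = CohortSpec(
            (GroupSpec("CTR", 3, {"M1": (1.0, 0.1)}, control=True),), seed=0
        )
        with pytest.raises(KeyError, match="M2"):
            simulate_cohort(spec, two_marker_panel)


class TestCohortSpecValidation:
    def test_exactly_one_control_required(self):
        with pytest.raises(ValueError, match="control"):
            CohortSpec((GroupSpec("A", 3, {"M": (1, 0.1)}),))

    def test_duplicate_group_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            CohortSpec(
                (
                    GroupSpec("A", 3, {"M": (1, 0.1)}, control=True),
                    GroupSpec("A", 3, {"M": (1, 0.1)}),
                )
            )

    def test_negative_summaries_rejected(self):
        with pytest.raises(ValueError):
            GroupSpec("A", 3, {"M": (-1.0, 0.1)})

    def test_subset_keeps_control_and_rejects_unknown(self):
        spec = default_cohort_spec()
        sub = spec.subset(["CTR", "GlycV"])
        assert {g.group_name for g in sub.groups} == {"CTR", "GlycV"}
        assert sub.control_label == "CTR"
        with pytest.raises(KeyError):
            spec.subset(["CTR", "NoSuchGroup"])


class TestDefaultCohort:
    def test_nine_groups_73_biopsies_22_columns(self):
        spec = default_cohort_spec()
        assert len(spec.groups) == 9
        assert sum(g.n for g in spec.groups) == 73
        assert all(len(g.per_marker) == 22 for g in spec.groups)
        assert spec.control_label == "CTR"

    def test_control_summaries_are_unit_mean(self):
        spec = default_cohort_spec()
        ctr = next(g for g in spec.groups if g.control)
        assert all(mean == 1.0 for mean, _ in ctr.per_marker.values())

    def test_glycv_pygm_is_absent(self):
        spec = default_cohort_spec()
        glycv = next(g for g in spec.groups if g.group_name == "GlycV")
        assert glycv.per_marker["PYGM"] == (0.0, 0.0)

    def test_load_from_mapping_round_trips(self):
        cfg = {
            "groups": {
                "CTR": {"n": 3, "control": True, "markers": {"M": [1.0, 0.1]}},
                "DIS": {"n": 2, "markers": {"M": [2.0, 0.3]}},
            }
        }
        spec = load_cohort_spec(cfg)
        assert spec.control_label == "CTR"
        assert spec.groups[1].per_marker["M"] == (2.0, 0.3)


class TestSimulateSpotTable:
    def test_spot_counts_per_marker(self, small_cohort_spec, two_marker_panel):
        expr = simulate_cohort(small_cohort_spec, two_marker_panel)
        layout = ArrayLayoutSpec(seed=5)
        spots = simulate_spot_table(expr, layout, default_curve_params(["M1", "M2"]))
        m1 = spots[spots["marker"] == "M1"]
        assert (m1["content_type"] == "standard").sum() == 6
        assert (m1["content_type"] == "blank").sum() == 4
        assert (m1["content_type"] == "sample").sum() == 9 * 4

    def test_noiseless_spots_are_exactly_linear(self, small_cohort_spec,
                                                two_marker_panel):
        expr = simulate_cohort(small_cohort_spec, two_marker_panel)
        layout = ArrayLayoutSpec(technical_cv_percent=0.0, seed=5)
        spots = simulate_spot_table(expr, layout, {"M1": (1000.0, 50.0),
                                                   "M2": (1000.0, 50.0)})
        row = spots[(spots["marker"] == "M1")
                    & (spots["sample_id"] == "CTR_01")].iloc[0]
        truth = expr.data.loc["CTR_01", "M1"]
        assert row["intensity"] == pytest.approx(1000.0 * truth + 50.0)

    def test_intensities_never_negative(self, small_cohort_spec, two_marker_panel):
        expr = simulate_cohort(small_cohort_spec, two_marker_panel)
        layout = ArrayLayoutSpec(technical_cv_percent=80.0, seed=5)
        spots = simulate_spot_table(expr, layout, default_curve_params(["M1", "M2"]))
        assert (spots["intensity"] >= 0).all()

    def test_nonpositive_slope_rejected(self, small_cohort_spec, two_marker_panel):
        expr = simulate_cohort(small_cohort_spec, two_marker_panel)
        with pytest.raises(ValueError, match="slope"):
            simulate_spot_table(expr, ArrayLayoutSpec(),
                                {"M1": (0.0, 50.0), "M2": (1000.0, 50.0)})

    def test_layout_validation(self):
        with pytest.raises(ValueError):
            ArrayLayoutSpec(replicates_per_sample=0)
        with pytest.raises(ValueError):
            ArrayLayoutSpec(standard_concentrations=(0.2, 0.6, 1.0))
        with pytest.raises(ValueError):
            ArrayLayoutSpec(technical_cv_percent=-1.0)
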