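"""Shared builders for small, fully in-memory test fixtures."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from myoarray import CohortSpec, ExpressionMatrix, GroupSpec
from myoarray.panel import Compartment, MarkerPanel


def make_matrix(values, sample_ids, labels, markers, units="fold_of_control"):
    data = pd.DataFrame(
        np.asarray(values, dtype=float),
        index=pd.Index(sample_ids, name="sample_id"),
        columns=markers,
    )
    classes = pd.Series(list(labels), index=data.index, name="class_label")
    return ExpressionMatrix(data, classes, units=units)


@pytest.fixture
def two_marker_panel():
    return MarkerPanel(
        markers=(("M1", Compartment.MITOCHONDRIAL), ("M2", Compartment.CYTOPLASMIC)),
        derived_ratios={},
    )


@pytest.fixture
def small_cohort_spec():
    """Two groups x two markers, no ratio columns."""
    return CohortSpec(
        (
            GroupSpec("CTR", 5, {"M1": (1.0, 0.1), "M2": (1.0, 0.1)}, control=True),
            GroupSpec("DIS", 4, {"M1": (2.0, 0.2), "M2": (0.5, 0.05)}),
        ),
        seed=7,
    )
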