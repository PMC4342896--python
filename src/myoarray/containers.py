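"""In-memory containers shared by all pipeline stages.

``ExpressionMatrix`` wraps a samples x markers :class:`pandas.DataFrame`
together with per-sample class labels and a unit flag; ``SpotTable`` is a
flat DataFrame of array spots with a fixed column set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Allowed unit flags for an ExpressionMatrix.
UNITS = ("calibrated", "fold_of_control", "log2_relative")

#: Column order of the SpotTable CSV dialect.
SPOT_COLUMNS = (
    "marker",
    "content_type",
    "sample_id",
    "class_label",
    "replicate_index",
    "nominal_concentration",
    "intensity",
)

#: Allowed spot content types.
CONTENT_TYPES = ("sample", "standard", "blank")


@dataclass
class ExpressionMatrix:
    """Samples x markers expression values with class labels.

    ``data`` is indexed by sample id with one column per marker (or derived
    ratio); ``classes`` maps sample id -> class label and shares the index
    of ``data``. ``units`` records the scale: raw calibrated amounts,
    fold of control, or log2 relative to the control mean.
    """

    data: pd.DataFrame
    classes: pd.Series
    units: str = "calibrated"
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.units not in UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected one of {UNITS}")
        if not self.data.index.equals(self.classes.index):
            raise ValueError("data and classes must share the same sample index")
        if self.units != "log2_relative":
            values = self.data.to_numpy(dtype=float)
            if np.any(values < 0):
                raise ValueError(
                    f"negative expression values not allowed in {self.units} units"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def markers(self) -> list[str]:
        return list(self.data.columns)

    def group_values(self, label: str) -> pd.DataFrame:
        """Rows belonging to one class label."""
        return self.data.loc[self.classes == label]

    def subset_markers(self, markers: list[str]) -> "ExpressionMatrix":
        missing = [m for m in markers if m not in self.data.columns]
        if missing:
            raise KeyError(f"markers not present: {missing}")
        return ExpressionMatrix(
            self.data[markers].copy(), self.classes.copy(), self.units, dict(self.flags)
        )

    def subset_classes(self, labels: list[str]) -> "ExpressionMatrix":
        keep = self.classes.isin(labels)
        return ExpressionMatrix(
            self.data.loc[keep].copy(),
            self.classes.loc[keep].copy(),
            self.units,
            dict(self.flags),
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.data.copy(), self.classes.copy(), self.units, dict(self.flags)
        )


def empty_spot_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in SPOT_COLUMNS})


def validate_spot_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check column set, content types, and non-negative intensities."""
    missing = [c for c in SPOT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"spot table missing columns: {missing}")
    if len(table):
        bad = set(table["content_type"]) - set(CONTENT_TYPES)
        if bad:
            raise ValueError(f"unknown spot content types: {sorted(bad)}")
        if (table["intensity"].astype(float) < 0).any():
            raise ValueError("spot intensities must be non-negative")
    return table
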