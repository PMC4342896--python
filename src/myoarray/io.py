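"""Flat-file dialects: expression CSV, spot CSV, Newick, YAML configs.

One CSV dialect per artifact type, UTF-8 with "." decimals:

* expression matrix: ``sample_id, class_label, <marker...>``
* spot table: ``marker, content_type, sample_id, class_label,
  replicate_index, nominal_concentration, intensity``
"""

from __future__ import annotations

import warnings

import pandas as pd

from .cluster import Linkage, linkage_to_newick
from .containers import SPOT_COLUMNS, ExpressionMatrix, validate_spot_table

__all__ = [
    "read_expression_csv",
    "write_expression_csv",
    "read_spot_csv",
    "write_spot_csv",
    "write_newick",
]


def write_expression_csv(expr: ExpressionMatrix, path) -> None:
    frame = expr.data.copy()
    frame.insert(0, "class_label", expr.classes)
    frame.index.name = "sample_id"
    frame.to_csv(path)


def read_expression_csv(path, units: str = "fold_of_control") -> ExpressionMatrix:
    try:
        frame = pd.read_csv(path, index_col=0)
    except pd.errors.EmptyDataError:
        warnings.warn(f"empty expression CSV: {path}", stacklevel=2)
        idx = pd.Index([], name="sample_id")
        return ExpressionMatrix(
            pd.DataFrame(index=idx), pd.Series(dtype=object, index=idx), units
        )
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed expression CSV {path}: {err}") from err
    if "class_label" not in frame.columns:
        raise ValueError(f"{path}: missing required column 'class_label'")
    classes = frame["class_label"].astype(str)
    data = frame.drop(columns="class_label").astype(float)
    data.index = data.index.astype(str)
    data.index.name = "sample_id"
    classes.index = data.index
    return ExpressionMatrix(data, classes, units)


def write_spot_csv(table: pd.DataFrame, path) -> None:
    validate_spot_table(table)
    table.to_csv(path, index=False)


def read_spot_csv(path) -> pd.DataFrame:
    try:
        table = pd.read_csv(
            path, dtype={"sample_id": str, "class_label": str}, keep_default_na=False,
            na_values=[""],
        )
    except pd.errors.EmptyDataError:
        warnings.warn(f"empty spot CSV: {path}", stacklevel=2)
        from .containers import empty_spot_table

        return empty_spot_table()
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed spot CSV {path}: {err}") from err
    missing = [c for c in SPOT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: spot CSV missing columns {missing}")
    table["sample_id"] = table["sample_id"].fillna("")
    table["class_label"] = table["class_label"].fillna("")
    return validate_spot_table(table)


def write_newick(linkage: Linkage, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(linkage_to_newick(linkage) + "\n")
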