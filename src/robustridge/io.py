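"""CSV dataset loading and provenance-stamped result serialization."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .core import RegressionData, standardize_design

__all__ = ["read_csv_dataset", "write_results", "to_jsonable"]


def read_csv_dataset(path: str | Path,
                     response_column: str) -> tuple[RegressionData, list[str]]:
    """Load a delimited dataset and standardize it.

    All non-response columns are treated as predictors and must parse as
    numbers; rows containing missing values are rejected (with their
    1-based row numbers) rather than silently dropped.

    Returns the standardized data and the predictor column names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path)
    if response_column not in df.columns:
        raise ValueError(f"missing response column {response_column!r}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ValueError(f"parse error at row {row}, column {col!r}")
        df[col] = coerced
    missing = df.isna().any(axis=1)
    if missing.any():
        rows = [int(i) + 1 for i in df.index[missing]]
        raise ValueError(f"missing value(s) in row(s) {rows}")
    predictors = [c for c in df.columns if c != response_column]
    if not predictors:
        raise ValueError("no predictor columns")
    data = standardize_design(df[predictors].to_numpy(float),
                              df[response_column].to_numpy(float))
    return data, predictors


def to_jsonable(obj: Any) -> Any:
    """Recursively convert results (dataclasses, arrays, enums) to JSON types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: to_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    if hasattr(obj, "value") and not isinstance(obj, (int, float, str, bool)):
        return obj.value  # enums
    return obj


def write_results(result: Any, path: str | Path, seed: int | None = None,
                  config_echo: dict | None = None) -> None:
    """Serialize a result record (JSON) or table (CSV) with provenance.

    DataFrames go to CSV; everything else becomes a JSON document
    embedding the package version, the seed and the full parameter echo.
    """
    path = Path(path)
    if isinstance(result, pd.DataFrame):
        result.to_csv(path, index=False)
        return
    doc = {
        "package_version": __version__,
        "seed": seed,
        "config": to_jsonable(config_echo) if config_echo else None,
        "result": to_jsonable(result),
    }
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
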