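"""CSV input/output for datasets, correlation matrices and result tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import Dataset

__all__ = [
    "read_dataset",
    "read_correlation",
    "write_frame",
    "render_table",
]


def read_dataset(path: str | Path, response: str) -> Dataset:
    """Read a header-rowed CSV into a :class:`~ridgepen.core.Dataset`.

    The response column is selected by name; every remaining column is a
    predictor.  Any row containing a non-numeric or missing cell is rejected
    with its (0-based, data-row) index in the error message.
    """
    df = pd.read_csv(path)
    if response not in df.columns:
        raise ValueError(
            f"response column {response!r} not in header: {list(df.columns)}"
        )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        idx = int(np.argmax(bad.to_numpy()))
        raise ValueError(f"non-numeric or missing cell in data row {idx}")
    y = numeric[response].to_numpy(dtype=float)
    predictors = numeric.drop(columns=[response])
    return Dataset(
        predictors=predictors.to_numpy(dtype=float),
        response=y,
        column_names=list(predictors.columns),
    ).validate()


def read_correlation(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a square correlation-matrix CSV (header row of column names)."""
    df = pd.read_csv(path)
    R = df.to_numpy(dtype=float)
    if R.shape[0] != R.shape[1]:
        raise ValueError(
            f"correlation matrix must be square, got shape {R.shape}"
        )
    return R, list(df.columns)


def write_frame(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def render_table(df: pd.DataFrame, float_fmt: str = "{:.4f}") -> str:
    """Aligned plain-text rendering of a result table."""
    if df.empty:
        raise ValueError("empty result table")
    formatted = df.copy()
    for col in formatted.columns:
        if pd.api.types.is_float_dtype(formatted[col]):
            formatted[col] = formatted[col].map(float_fmt.format)
    return formatted.to_string(index=False)
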