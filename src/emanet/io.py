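"""Reading and writing beep-level EMA tables.

Dialect: UTF-8 comma-separated values with header
``person_id,day,occasion,scheduled_time,response_time,completion_seconds,
neg_affect,pos_affect,neg_cognition,pos_cognition,rigidity,variation``,
ISO-8601 timestamps, and an empty field encoding a missing value. A missed
prompt is a row whose six item scores are all empty.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import ITEM_COLUMNS

COLUMNS = [
    "person_id", "day", "occasion", "scheduled_time", "response_time",
    "completion_seconds", *ITEM_COLUMNS,
]

_TIME_COLS = ["scheduled_time", "response_time"]


def write_dataset(ds: pd.DataFrame, path: str | Path) -> None:
    """Write a beep-level dataset as CSV (empty field = missing)."""
    missing = [c for c in COLUMNS if c not in ds.columns]
    if missing:
        raise ValueError(f"dataset is missing columns: {missing}")
    out = ds[COLUMNS].copy()
    for col in _TIME_COLS:
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, na_rep="")


def read_dataset(path: str | Path, validate_range: bool = True) -> pd.DataFrame:
    """Read and validate a beep-level dataset.

    Checks: expected header, unique (person_id, day, occasion), item scores
    all-present or all-missing per row, and (by default) scores within the
    0-100 response scale. Errors name the offending CSV line (header = line 1).
    """
    try:
        ds = pd.read_csv(path, dtype={"person_id": str})
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    missing = [c for c in COLUMNS if c not in ds.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    ds = ds[COLUMNS]
    for col in _TIME_COLS:
        try:
            ds[col] = pd.to_datetime(ds[col], format="ISO8601")
        except ValueError as exc:
            raise ValueError(f"{path}: bad timestamp in column {col}: {exc}") from exc

    dup = ds.duplicated(subset=["person_id", "day", "occasion"])
    if dup.any():
        line = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise ValueError(f"{path}: duplicate (person_id, day, occasion) at line {line}")

    scores = ds[ITEM_COLUMNS].to_numpy(dtype=float)
    n_present = (~np.isnan(scores)).sum(axis=1)
    partial = (n_present > 0) & (n_present < len(ITEM_COLUMNS))
    if partial.any():
        line = int(np.flatnonzero(partial)[0]) + 2
        raise ValueError(
            f"{path}: line {line} has a partially answered prompt "
            "(scores must be all present or all missing)"
        )
    if validate_range:
        with np.errstate(invalid="ignore"):
            bad = np.nan_to_num(scores, nan=50.0)
            out_of_range = (bad < 0.0) | (bad > 100.0)
        if out_of_range.any():
            r, c = np.argwhere(out_of_range)[0]
            raise ValueError(
                f"{path}: line {int(r) + 2} has out-of-range score "
                f"{scores[r, c]:g} in column {ITEM_COLUMNS[int(c)]}"
            )
    return ds
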