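"""Long-format plate-table schemas (growth OD600 and dual-luciferase).

Both tables travel as validated :class:`pandas.DataFrame` objects. The growth
table holds one row per well per timepoint; the reporter table one row per
well. Validation is strict: a missing column or a series that deviates from
the shared time grid is an error, not a warning.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: strain label for no-bacteria blank wells
BLANK = "BLANK"
#: protein label for wells without added protein
NO_PROTEIN = "NONE"
#: reporter-table labels
VECTOR = "VECTOR"
VEHICLE = "VEHICLE"

GROWTH_COLUMNS = [
    "strain",
    "protein",
    "concentration",
    "replicate_bio",
    "replicate_tech",
    "well",
    "time",
    "od600",
]
REPORTER_COLUMNS = ["complex", "treatment", "replicate", "firefly", "renilla"]

GROWTH_SERIES_KEY = [
    "strain",
    "protein",
    "concentration",
    "replicate_bio",
    "replicate_tech",
    "well",
]


class TableError(ValueError):
    """Raised for schema or grid violations in plate tables."""


def _require_columns(df: pd.DataFrame, columns: Iterable[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableError(f"{what} table is missing column(s): {', '.join(missing)}")


def validate_growth_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate schema and time-grid uniformity; returns a typed copy."""
    _require_columns(df, GROWTH_COLUMNS, "growth")
    df = df.loc[:, GROWTH_COLUMNS].copy()
    df["concentration"] = df["concentration"].astype(float)
    df["time"] = df["time"].astype(float)
    df["od600"] = df["od600"].astype(float)
    df["replicate_bio"] = df["replicate_bio"].astype(int)
    df["replicate_tech"] = df["replicate_tech"].astype(int)
    if (df["concentration"] < 0).any():
        raise TableError("negative concentration in growth table")

    grid: np.ndarray | None = None
    for key, sub in df.groupby(GROWTH_SERIES_KEY, sort=False):
        t = sub["time"].to_numpy()
        if not np.all(np.diff(t) > 0):
            raise TableError(f"series {key}: time grid not strictly increasing")
        if grid is None:
            grid = t
        elif len(t) != len(grid) or not np.allclose(t, grid):
            raise TableError(f"series {key}: time grid differs from the plate grid")
    return df


def read_growth_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format OD600 growth CSV."""
    df = pd.read_csv(path)
    try:
        return validate_growth_table(df)
    except TableError as exc:
        raise TableError(f"{path}: {exc}") from exc


def validate_reporter_table(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, REPORTER_COLUMNS, "reporter")
    df = df.loc[:, REPORTER_COLUMNS].copy()
    df["replicate"] = df["replicate"].astype(int)
    df["firefly"] = df["firefly"].astype(float)
    df["renilla"] = df["renilla"].astype(float)
    if (df["firefly"] < 0).any() or (df["renilla"] < 0).any():
        raise TableError("negative luminescence in reporter table")
    return df


def read_reporter_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format dual-luciferase CSV."""
    df = pd.read_csv(path)
    try:
        return validate_reporter_table(df)
    except TableError as exc:
        raise TableError(f"{path}: {exc}") from exc


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a plate table as comma-separated UTF-8 with header."""
    df.to_csv(path, index=False)
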