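"""Readers and writers for footprint measurement tables.

CSV is the interchange format (RFC-4180, UTF-8, header row required).
Empty cells denote missing values and survive a round-trip; numeric cells
may use either a decimal point or a decimal comma on input (the source
tables mix both), and are always written back with a decimal point.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .records import MEASUREMENT_COLUMNS, FootprintTable, validate_table

FIXTURE_NAMES = ("table2", "table3", "table4")

_NUMERIC_EXTRA = {"morphotype", "in_summary", "in_situ", "cast_1950"}


def _is_numeric_column(col: str) -> bool:
    return col in MEASUREMENT_COLUMNS or col in _NUMERIC_EXTRA or col.endswith("_printed")


class FootprintTableError(ValueError):
    """Malformed measurement table (bad cell, duplicate id, negative value)."""


def _parse_cell(raw: str, row: str, col: str) -> float:
    txt = raw.strip().replace("−", "-")
    if txt in ("", "-"):
        return np.nan
    txt = txt.replace(",", ".")
    try:
        val = float(txt)
    except ValueError:
        raise FootprintTableError(
            f"unparseable numeric cell {raw!r} at row {row!r}, column {col!r}"
        ) from None
    return val


def read_footprint_table(
    path: Union[str, Path],
    dialect: Optional[dict] = None,
) -> FootprintTable:
    """Read a measurement CSV into a validated :class:`FootprintTable`.

    Parameters
    ----------
    path:
        CSV file with a header naming the measurement fields.
    dialect:
        Optional overrides passed to :func:`pandas.read_csv`
        (e.g. ``{"sep": ";"}``).

    Raises
    ------
    FootprintTableError
        On an unparseable numeric cell (named by row and column), a
        duplicate footprint id, or a negative measurement.
    """
    kwargs = dict(dtype=str, keep_default_na=False)
    if dialect:
        kwargs.update(dialect)
    raw = pd.read_csv(path, **kwargs)
    if "footprint_id" not in raw.columns:
        raise FootprintTableError(f"{path}: missing 'footprint_id' header")

    out = {}
    for col in raw.columns:
        if _is_numeric_column(col):
            out[col] = [
                _parse_cell(v, rid, col)
                for v, rid in zip(raw[col], raw["footprint_id"])
            ]
        else:
            out[col] = raw[col].str.strip().replace({"": None})
    df = pd.DataFrame(out, columns=raw.columns)

    ids = df["footprint_id"]
    if ids.duplicated().any():
        dup = sorted(ids[ids.duplicated()].unique())
        raise FootprintTableError(f"duplicate footprint_id values: {dup}")
    for col in MEASUREMENT_COLUMNS:
        if col in df.columns:
            bad = df[col].astype(float) < 0
            if bad.any():
                rid = df.loc[bad, "footprint_id"].iloc[0]
                raise FootprintTableError(
                    f"negative measurement in column {col!r}, row {rid!r}"
                )
    return FootprintTable(df)


def write_footprint_table(table: FootprintTable, path: Union[str, Path]) -> None:
    """Write a table to CSV; missing cells become empty strings."""
    table.data.to_csv(path, index=False, na_rep="")


def _fixture_path(name: str) -> Path:
    res = importlib.resources.files("ichnometry.datasets") / f"{name}.csv"
    return Path(str(res))


def load_basura_fixtures(which: str) -> FootprintTable:
    """Load one of the packaged Bàsura cave tables.

    ``table2``: qualitative shape descriptors and published morphotype
    labels (26 footprints).  ``table3``: full measurement block with the
    printed foot index / stature / body-mass / age cells carried along as
    ``*_printed`` columns (26 footprints).  ``table4``: the nine-variable
    matrix used for the PCA (23 footprints, with missing cells).

    Note the transcription preserves the source's internal discrepancies
    as printed, e.g. SM26 is recorded as a right foot in the measurement
    block but a left foot among the descriptors.
    """
    if which not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {which!r}; expected one of {FIXTURE_NAMES}")
    table = read_footprint_table(_fixture_path(which))
    if which == "table3":
        desc = read_footprint_table(_fixture_path("table2")).data
        table = FootprintTable(table.data, descriptors=desc)
    return table


def load_summary_fixture() -> pd.DataFrame:
    """Published per-morphotype summary rows (mean ± SD cells as printed)."""
    df = pd.read_csv(_fixture_path("table3_summary"))
    return df


def write_report(estimates: Iterable, path: Union[str, Path]) -> None:
    """Write per-footprint and per-morphotype biometric reports.

    ``path`` is the per-footprint CSV; a ``*_summary.csv`` and a
    human-readable ``*.txt`` replicating the published table layout are
    written alongside.  Delegates to :mod:`ichnometry.report`.
    """
    from .report import write_report_files

    write_report_files(list(estimates), Path(path))
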