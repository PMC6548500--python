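"""Data model for footprint measurement tables.

A footprint is described by up to nine baseline lengths (digit tips 1-5 and
the ball/arch/heel landmarks to the heel baseline), three transverse widths,
a toe-declination angle, the maximum foot length and width, and the arch
angle.  All linear measurements are in centimetres, angles in degrees.
Any measurement may be missing (soft substrate, partial preservation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np
import pandas as pd

#: All numeric measurement columns, in canonical order.
MEASUREMENT_COLUMNS = [
    "Dt1_BL", "Dt2_BL", "Dt3_BL", "Dt4_BL", "Dt5_BL",
    "mtm_BL", "mtl_BL", "ntu_BL", "mttu_BL", "ccm_BL", "ctul_BL",
    "mtm_horiz", "mttu_horiz", "ctul_horiz",
    "T1_T5", "max_FL", "max_FW", "Aa",
]

#: The nine variables entering the principal component analysis.
PCA_VARIABLES = [
    "Dt1_BL", "Dt2_BL", "Dt3_BL",
    "mtm_BL", "mtl_BL", "ccm_BL", "ctul_BL",
    "mtm_horiz", "ctul_horiz",
]

#: Length/width columns that must be strictly positive when present.
POSITIVE_COLUMNS = [c for c in MEASUREMENT_COLUMNS if c not in ("T1_T5", "Aa")]

SIDES = {"left", "right", "L", "R"}


@dataclass
class FootprintMeasurement:
    """One footprint's landmark measurements (cm / degrees); None = missing."""

    footprint_id: str
    side: Optional[str] = None
    source: Optional[str] = None
    Dt1_BL: Optional[float] = None
    Dt2_BL: Optional[float] = None
    Dt3_BL: Optional[float] = None
    Dt4_BL: Optional[float] = None
    Dt5_BL: Optional[float] = None
    mtm_BL: Optional[float] = None
    mtl_BL: Optional[float] = None
    ntu_BL: Optional[float] = None
    mttu_BL: Optional[float] = None
    ccm_BL: Optional[float] = None
    ctul_BL: Optional[float] = None
    mtm_horiz: Optional[float] = None
    mttu_horiz: Optional[float] = None
    ctul_horiz: Optional[float] = None
    T1_T5: Optional[float] = None
    max_FL: Optional[float] = None
    max_FW: Optional[float] = None
    Aa: Optional[float] = None

    @classmethod
    def from_series(cls, s: pd.Series) -> "FootprintMeasurement":
        kwargs = {"footprint_id": str(s["footprint_id"])}
        for f in fields(cls):
            if f.name == "footprint_id" or f.name not in s.index:
                continue
            v = s[f.name]
            if isinstance(v, float) and np.isnan(v):
                v = None
            kwargs[f.name] = v
        return cls(**kwargs)


@dataclass
class FootprintTable:
    """Ordered collection of footprint measurements plus optional descriptors.

    ``data`` is a DataFrame with a ``footprint_id`` column (unique) and any
    subset of :data:`MEASUREMENT_COLUMNS`; extra columns (printed indices,
    morphotype labels, provenance flags) are carried through untouched.
    Units are fixed: centimetres for lengths/widths, degrees for angles.
    """

    data: pd.DataFrame
    descriptors: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if "footprint_id" not in self.data.columns:
            raise ValueError("FootprintTable requires a 'footprint_id' column")
        ids = self.data["footprint_id"]
        if ids.duplicated().any():
            dup = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate footprint_id values: {dup}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def footprint_ids(self) -> list[str]:
        return list(self.data["footprint_id"])

    def records(self) -> list[FootprintMeasurement]:
        return [FootprintMeasurement.from_series(r) for _, r in self.data.iterrows()]

    def measurement_matrix(self, columns: Optional[list[str]] = None) -> pd.DataFrame:
        """Footprint-by-variable matrix (NaN = missing), indexed by id.

        Defaults to the nine PCA variables; columns absent from the table
        are dropped.
        """
        cols = PCA_VARIABLES if columns is None else columns
        cols = [c for c in cols if c in self.data.columns]
        m = self.data.set_index("footprint_id")[cols].astype(float)
        m.index = m.index.astype(str)
        return m

    def subset(self, ids: list[str]) -> "FootprintTable":
        mask = self.data["footprint_id"].isin(ids)
        desc = None
        if self.descriptors is not None:
            desc = self.descriptors[
                self.descriptors["footprint_id"].isin(ids)
            ].reset_index(drop=True)
        return FootprintTable(self.data[mask].reset_index(drop=True), desc)


def validate_record(r: FootprintMeasurement | pd.Series | dict) -> list[str]:
    """Return invariant violations for one footprint record (never raises).

    Checked: present lengths/widths strictly positive; max_FL >= max_FW;
    arch angle in (0, 90); side from the left/right vocabulary.
    """
    if isinstance(r, pd.Series):
        r = FootprintMeasurement.from_series(r)
    elif isinstance(r, dict):
        r = FootprintMeasurement(**r)
    issues: list[str] = []
    for col in POSITIVE_COLUMNS:
        v = getattr(r, col)
        if v is not None and not v > 0:
            issues.append(f"{r.footprint_id}: {col} must be > 0, got {v}")
    if r.max_FL is not None and r.max_FW is not None and r.max_FW > r.max_FL:
        issues.append(
            f"{r.footprint_id}: max_FW ({r.max_FW}) exceeds max_FL ({r.max_FL})"
        )
    if r.Aa is not None and not (0 < r.Aa < 90):
        issues.append(f"{r.footprint_id}: arch angle Aa must lie in (0, 90), got {r.Aa}")
    if r.side is not None and str(r.side) not in SIDES:
        issues.append(f"{r.footprint_id}: side must be left/right, got {r.side!r}")
    return issues


def validate_table(table: FootprintTable) -> dict[str, list[str]]:
    """Per-footprint invariant violations for a whole table (empty = clean)."""
    out: dict[str, list[str]] = {}
    for rec in table.records():
        issues = validate_record(rec)
        if issues:
            out[rec.footprint_id] = issues
    return out
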