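"""Reading, validating and subsetting calibration tables of crocodilian measurements.

A calibration table holds one row per specimen (or per species mean) with any
subset of the five morphometric variables used by the estimation chain:

======  =============================  =====
role    meaning                        units
======  =============================  =====
dcl     dorsal cranial (skull) length  mm
svl     snout-vent length              cm
ttl     total length                   cm
bm      body mass                      kg
bf      sustained bite force           N
======  =============================  =====

Missing cells are allowed; each bivariate regression uses only the rows where
both of its variables are present (pairwise-complete deletion), because the
estimation chain fits four separate bivariate models rather than one joint
model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

#: Valid measurement roles, in canonical column order.
ROLES: tuple[str, ...] = ("dcl", "svl", "ttl", "bm", "bf")

#: Units of each measurement role.
UNITS: dict[str, str] = {
    "dcl": "mm",
    "svl": "cm",
    "ttl": "cm",
    "bm": "kg",
    "bf": "N",
}


class CalibrationError(ValueError):
    """Raised when a calibration table violates its validity contract."""


@dataclass(frozen=True)
class MeasurementRecord:
    """One specimen's measurements; absent values are ``None``.

    Every present measurement must be strictly positive and finite, and at
    least one measurement must be present.
    """

    specimen_id: str
    species: str = ""
    dcl: float | None = None
    svl: float | None = None
    ttl: float | None = None
    bm: float | None = None
    bf: float | None = None

    def __post_init__(self) -> None:
        present = 0
        for role in ROLES:
            value = getattr(self, role)
            if value is None:
                continue
            present += 1
            if not np.isfinite(value) or value <= 0:
                raise CalibrationError(
                    f"record {self.specimen_id!r}: {role} = {value!r} "
                    "is not a strictly positive finite number"
                )
        if present == 0:
            raise CalibrationError(
                f"record {self.specimen_id!r} has no measurements"
            )

    def get(self, role: str) -> float | None:
        if role not in ROLES:
            raise CalibrationError(f"unknown measurement role {role!r}")
        return getattr(self, role)


@dataclass
class CalibrationTable:
    """An ordered, validated collection of measurement records.

    Parameters
    ----------
    records:
        The measurement records, in file order.
    source_label:
        Free-text provenance (e.g. which dataset the table emulates).
    """

    records: list[MeasurementRecord]
    source_label: str = ""
    _index: dict[str, int] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise CalibrationError("calibration table is empty")
        seen: set[str] = set()
        for rec in self.records:
            if rec.specimen_id in seen:
                raise CalibrationError(
                    f"duplicate specimen_id {rec.specimen_id!r}"
                )
            seen.add(rec.specimen_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def paired_view(self, x_role: str, y_role: str) -> np.ndarray:
        """Extract pairwise-complete ``(x, y)`` values for one regression.

        Returns an array of shape ``(m, 2)`` holding, in input order, the rows
        where both roles are present. Raises :class:`CalibrationError` when
        fewer than 3 complete pairs exist (too few to fit a line).
        """
        if x_role not in ROLES or y_role not in ROLES:
            raise CalibrationError(
                f"unknown role in ({x_role!r}, {y_role!r})"
            )
        if x_role == y_role:
            raise CalibrationError("x_role and y_role must differ")
        pairs = [
            (rec.get(x_role), rec.get(y_role))
            for rec in self.records
            if rec.get(x_role) is not None and rec.get(y_role) is not None
        ]
        if len(pairs) < 3:
            raise CalibrationError(
                f"only {len(pairs)} complete ({x_role}, {y_role}) pairs; "
                "at least 3 are required"
            )
        return np.asarray(pairs, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        """Render the table as a DataFrame (absent measurements become NaN)."""
        rows = []
        for rec in self.records:
            row: dict[str, object] = {
                "specimen_id": rec.specimen_id,
                "species": rec.species,
            }
            for role in ROLES:
                value = rec.get(role)
                row[role] = np.nan if value is None else value
            rows.append(row)
        return pd.DataFrame(rows, columns=["specimen_id", "species", *ROLES])


def read_calibration(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    source_label: str = "",
) -> CalibrationTable:
    """Read a CSV calibration file into a validated :class:`CalibrationTable`.

    Parameters
    ----------
    path:
        Comma-delimited UTF-8 text file with a header row.
    column_map:
        Mapping of file column names to measurement roles, e.g.
        ``{"DCL_mm": "dcl", "SVL_cm": "svl"}``. Unmapped columns are ignored.
        An ``id``/``specimen_id`` column is picked up automatically unless
        mapped explicitly (role ``"specimen_id"``); likewise ``species``. When
        ``column_map`` is ``None``, columns named exactly after the roles are
        used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"calibration file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    column_map = dict(column_map) if column_map else {}

    role_to_col: dict[str, str] = {}
    for col, role in column_map.items():
        if role not in (*ROLES, "specimen_id", "species"):
            raise CalibrationError(f"unknown role {role!r} for column {col!r}")
        if role in role_to_col:
            raise CalibrationError(f"role {role!r} mapped more than once")
        if col not in df.columns:
            raise CalibrationError(f"column {col!r} not in file {path}")
        role_to_col[role] = col
    for role in ROLES:
        if role not in role_to_col and role in df.columns:
            role_to_col[role] = role
    if "specimen_id" not in role_to_col:
        for candidate in ("specimen_id", "id"):
            if candidate in df.columns:
                role_to_col["specimen_id"] = candidate
                break
        else:
            raise CalibrationError(f"no specimen id column found in {path}")
    if "species" not in role_to_col and "species" in df.columns:
        role_to_col["species"] = "species"

    records: list[MeasurementRecord] = []
    for i, row in df.iterrows():
        kwargs: dict[str, object] = {
            "specimen_id": str(row[role_to_col["specimen_id"]]),
            "species": str(row[role_to_col["species"]])
            if "species" in role_to_col
            else "",
        }
        for role in ROLES:
            col = role_to_col.get(role)
            if col is None:
                continue
            raw = row[col]
            if pd.isna(raw) or (isinstance(raw, str) and not raw.strip()):
                continue
            try:
                value = float(raw)
            except (TypeError, ValueError) as exc:
                raise CalibrationError(
                    f"row {i} ({path.name}), column {col!r}: "
                    f"non-numeric value {raw!r}"
                ) from exc
            kwargs[role] = value
        try:
            records.append(MeasurementRecord(**kwargs))  # type: ignore[arg-type]
        except CalibrationError as exc:
            raise CalibrationError(
                f"row {i} ({path.name}): {exc}"
            ) from exc
    return CalibrationTable(records, source_label=source_label or path.name)


def write_calibration(table: CalibrationTable, path: str | Path) -> None:
    """Write a calibration table as CSV, mirroring the input schema."""
    # %.17g round-trips IEEE doubles exactly
    table.to_frame().to_csv(path, index=False, float_format="%.17g")


def paired_view(
    table: CalibrationTable, x_role: str, y_role: str
) -> np.ndarray:
    """Functional alias for :meth:`CalibrationTable.paired_view`."""
    return table.paired_view(x_role, y_role)
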