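"""Readers and writers for analyser-style gas-exchange tables.

The canonical on-disk form is a comma-separated UTF-8 file with a header
row, one row per steady-state observation, grouped into curves by a
``curve_id`` column.  Instrument exports with different headers or units
are ingested through a :class:`ColumnMapping` that names the source
column and declared unit for each canonical field; all unit conversion
happens here, at the I/O boundary, so the rest of the package only ever
sees canonical units.  Malformed rows are collected into an error report
and never silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .records import CANONICAL_FIELDS, GasExchangeRecord, ResponseCurve

__all__ = [
    "SchemaError",
    "UnitError",
    "ColumnMapping",
    "RowError",
    "TableReadResult",
    "read_gas_exchange_table",
    "write_gas_exchange_csv",
]

REQUIRED_FIELDS = ("A", "gs_w", "ci", "ca", "PAR")
OPTIONAL_FIELDS = tuple(f for f in CANONICAL_FIELDS if f not in REQUIRED_FIELDS)

# Scale factors to canonical units, keyed by unit-dimension class.
_UNIT_SCALES: dict[str, dict[str, float]] = {
    "flux_area": {  # canonical µmol m-2 s-1
        "µmol m-2 s-1": 1.0, "umol m-2 s-1": 1.0,
        "mmol m-2 s-1": 1e3, "mol m-2 s-1": 1e6,
    },
    "conductance": {  # canonical mol m-2 s-1
        "mol m-2 s-1": 1.0, "mmol m-2 s-1": 1e-3, "µmol m-2 s-1": 1e-6,
        "umol m-2 s-1": 1e-6,
    },
    "mole_fraction": {  # canonical µmol mol-1
        "µmol mol-1": 1.0, "umol mol-1": 1.0, "ppm": 1.0,
        "mmol mol-1": 1e3, "mol mol-1": 1e6,
    },
    "pressure": {"kPa": 1.0, "Pa": 1e-3, "hPa": 0.1, "bar": 100.0},
    "temperature": {"degC": 1.0},
    "flow": {"µmol s-1": 1.0, "umol s-1": 1.0, "mmol s-1": 1e3},
    "dimensionless": {"dimensionless": 1.0, "": 1.0},
}

_FIELD_DIMENSION = {
    "A": "flux_area", "gs_w": "conductance", "ci": "mole_fraction",
    "ca": "mole_fraction", "PAR": "flux_area", "Tleaf": "temperature",
    "VPD": "pressure", "flow": "flow", "phi_PSII": "dimensionless",
    "Patm": "pressure", "c_ambient": "mole_fraction",
}


class SchemaError(ValueError):
    """The file's columns do not cover the required canonical fields."""


class UnitError(ValueError):
    """A declared unit is unknown for the field's dimension."""


@dataclass(frozen=True)
class ColumnMapping:
    """Maps canonical field names to (source column, declared unit).

    ``columns`` entries are ``field -> (header, unit)``; omitted fields
    fall back to a column with the canonical name and unit.  Each
    required field must be mapped (or present canonically) exactly once.
    """

    columns: dict[str, tuple[str, str]] = field(default_factory=dict)
    curve_id_column: str = "curve_id"
    curve_type_column: str = "curve_type"

    def source_for(self, fieldname: str) -> tuple[str, str]:
        if fieldname in self.columns:
            return self.columns[fieldname]
        return fieldname, CANONICAL_FIELDS[fieldname]

    def scale_for(self, fieldname: str) -> float:
        _, unit = self.source_for(fieldname)
        scales = _UNIT_SCALES[_FIELD_DIMENSION[fieldname]]
        if unit not in scales:
            raise UnitError(
                f"unknown unit {unit!r} for field {fieldname!r} "
                f"(known: {sorted(scales)})"
            )
        return scales[unit]


@dataclass(frozen=True)
class RowError:
    """One malformed row: curve id, 0-based row index, and the reason."""

    curve_id: str
    row: int
    reason: str


@dataclass
class TableReadResult:
    """Curves parsed from a file plus the report of rejected rows."""

    curves: list[ResponseCurve]
    errors: list[RowError]

    def __iter__(self):
        return iter(self.curves)


def read_gas_exchange_table(
    path: str | Path, mapping: ColumnMapping | None = None
) -> TableReadResult:
    """Read a delimited gas-exchange log into grouped response curves.

    Raises :class:`SchemaError` if the file is empty or a required field
    has no source column; rows that fail numeric conversion are recorded
    in the result's ``errors`` list with their curve id and row index.
    """
    mapping = mapping or ColumnMapping()
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    missing = [
        f for f in REQUIRED_FIELDS if mapping.source_for(f)[0] not in df.columns
    ]
    if missing:
        raise SchemaError(f"{path}: unmapped required fields {missing}")
    if mapping.curve_id_column not in df.columns:
        raise SchemaError(f"{path}: no curve-id column {mapping.curve_id_column!r}")

    errors: list[RowError] = []
    curves: list[ResponseCurve] = []
    for curve_id, sub in df.groupby(mapping.curve_id_column, sort=False):
        records = []
        if mapping.curve_type_column in sub.columns:
            curve_type = str(sub[mapping.curve_type_column].iloc[0])
        else:
            curve_type = "aci"
        for idx, row in sub.iterrows():
            values: dict[str, float | None] = {}
            bad = None
            for fieldname in CANONICAL_FIELDS:
                col, _ = mapping.source_for(fieldname)
                if col not in sub.columns:
                    if fieldname in REQUIRED_FIELDS:
                        bad = f"missing column {col}"
                        break
                    values[fieldname] = None
                    continue
                raw = row[col]
                if pd.isna(raw):
                    if fieldname in REQUIRED_FIELDS:
                        bad = f"missing value in {col}"
                        break
                    values[fieldname] = None
                    continue
                try:
                    values[fieldname] = float(raw) * mapping.scale_for(fieldname)
                except (TypeError, ValueError):
                    bad = f"non-numeric value {raw!r} in {col}"
                    break
            if bad is not None:
                errors.append(RowError(curve_id=str(curve_id), row=int(idx), reason=bad))
                continue
            defaults = GasExchangeRecord(A=0, gs_w=0, ci=0, ca=1, PAR=0)
            for fieldname in ("Tleaf", "VPD", "flow", "Patm"):
                if values.get(fieldname) is None:
                    values[fieldname] = getattr(defaults, fieldname)
            flags: tuple[str, ...] = ()
            if "qc_flags" in sub.columns and isinstance(row.get("qc_flags"), str):
                flags = tuple(x for x in row["qc_flags"].split(";") if x)
            leak = bool(row.get("leak_corrected", False))
            records.append(
                GasExchangeRecord(
                    **values, leak_corrected=leak, qc_flags=flags  # type: ignore[arg-type]
                )
            )
        if records:
            curves.append(
                ResponseCurve(
                    curve_type=curve_type, records=records,
                    metadata={"curve_id": str(curve_id), "source": str(path)},
                )
            )
    return TableReadResult(curves=curves, errors=errors)


def write_gas_exchange_csv(curves: list[ResponseCurve], path: str | Path) -> None:
    """Write curves to the canonical CSV schema the reader consumes."""
    frames = []
    for i, curve in enumerate(curves):
        df = curve.to_dataframe()
        df.insert(0, "curve_id", curve.metadata.get("curve_id", f"curve{i}"))
        df.insert(1, "curve_type", curve.curve_type)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False)
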