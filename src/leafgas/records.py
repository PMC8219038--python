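"""In-memory containers for gas-exchange observations and response curves."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Any, Iterator

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import SyntheticTruth

__all__ = ["GasExchangeRecord", "ResponseCurve", "CANONICAL_FIELDS"]

#: Canonical record fields and their units, in writer column order.
CANONICAL_FIELDS: dict[str, str] = {
    "A": "µmol m-2 s-1",
    "gs_w": "mol m-2 s-1",
    "ci": "µmol mol-1",
    "ca": "µmol mol-1",
    "PAR": "µmol m-2 s-1",
    "Tleaf": "degC",
    "VPD": "kPa",
    "flow": "µmol s-1",
    "phi_PSII": "dimensionless",
    "Patm": "kPa",
    "c_ambient": "µmol mol-1",
}


@dataclass(frozen=True)
class GasExchangeRecord:
    """One steady-state cuvette observation.

    Fluxes and mole fractions are in the canonical units of
    :data:`CANONICAL_FIELDS`: A in µmol m⁻² s⁻¹, gs_w (stomatal
    conductance to *water vapour*) in mol m⁻² s⁻¹, CO2 mole fractions in
    µmol mol⁻¹.  ``phi_PSII`` is the PSII operating efficiency from
    concurrent chlorophyll fluorescence, if measured.  ``c_ambient`` is
    the CO2 mole fraction of the air surrounding the chamber, used by the
    leak correction.
    """

    A: float
    gs_w: float
    ci: float
    ca: float
    PAR: float
    Tleaf: float = 25.0
    VPD: float = 1.5
    flow: float = 300.0
    phi_PSII: float | None = None
    Patm: float = 101.325
    c_ambient: float | None = None
    leak_corrected: bool = False
    qc_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        flags = list(self.qc_flags)
        if self.ca <= 0 and "nonpositive_ca" not in flags:
            flags.append("nonpositive_ca")
        if self.gs_w < 0 and "negative_gs" not in flags:
            flags.append("negative_gs")
        if self.A > 0 and self.ci > self.ca and "ci_above_ca" not in flags:
            flags.append("ci_above_ca")
        if flags != list(self.qc_flags):
            object.__setattr__(self, "qc_flags", tuple(flags))

    def with_(self, **kwargs: Any) -> "GasExchangeRecord":
        return replace(self, **kwargs)


@dataclass
class ResponseCurve:
    """An ordered set of records forming one measured response curve.

    ``curve_type`` is one of ``"aci"``, ``"light"`` or ``"laisk"``;
    a Laisk sub-curve holds PAR constant across its records.  ``truth``
    carries the generating parameter set for synthetic curves.
    """

    curve_type: str
    records: list[GasExchangeRecord]
    metadata: dict[str, Any] = field(default_factory=dict)
    truth: "SyntheticTruth | None" = None

    def __post_init__(self) -> None:
        if self.curve_type not in ("aci", "light", "laisk"):
            raise ValueError(f"unknown curve_type {self.curve_type!r}")
        if self.curve_type == "laisk" and self.records:
            pars = {r.PAR for r in self.records}
            if len(pars) > 1:
                raise ValueError("laisk sub-curve must hold PAR constant")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GasExchangeRecord]:
        return iter(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        """Records as a DataFrame with canonical columns plus flags."""
        rows = []
        for r in self.records:
            row = {f: getattr(r, f) for f in CANONICAL_FIELDS}
            row["leak_corrected"] = r.leak_corrected
            row["qc_flags"] = ";".join(r.qc_flags)
            rows.append(row)
        return pd.DataFrame(rows)
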