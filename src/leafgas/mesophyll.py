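"""Variable-J estimation of mesophyll conductance with the δCc/δA filter.

The variable-J method inverts the RuBP-regeneration-limited FvCB equation
point by point.  Given net assimilation A, intercellular CO2 ci, electron
transport J, day respiration Rd and the apparent photorespiratory
compensation point ci*, the mesophyll conductance is

    gm = A / ( ci - ci* [J + 8(A+Rd)] / [J - 4(A+Rd)] )

and the chloroplastic CO2 follows as cc = ci - A/gm.  The reliability of
each estimate is judged by the sensitivity of the inferred cc to errors
in A,

    δCc/δA = 12 ci* J / [J - 4(A+Rd)]²,

and only records with 10 < δCc/δA < 50 (strict) are retained for
aggregation; the rest are kept but flagged.

J can come from two routes: under non-photorespiratory conditions
(1% O2) it is fixed entirely by gas exchange, J = 4(A+Rd); under normal
air it is taken from concurrent chlorophyll fluorescence,
J = ΦPSII · PAR · absorptance · β, with leaf absorptance 0.84 and PSII
light-partitioning fraction β = 0.5 by default (field conventions; both
configurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import pandas as pd

__all__ = [
    "ABSORPTANCE_DEFAULT",
    "BETA_DEFAULT",
    "QCReason",
    "GmEstimate",
    "j_nonphotorespiratory",
    "j_from_fluorescence",
    "gm_variable_j",
    "cc_from_gm",
    "estimate_gm_batch",
]

#: Default leaf absorptance used in the fluorescence route to J.
ABSORPTANCE_DEFAULT = 0.84
#: Default fraction of absorbed quanta partitioned to PSII.
BETA_DEFAULT = 0.5

#: Strict reliability window on δCc/δA.
DCC_DA_LOW = 10.0
DCC_DA_HIGH = 50.0

# |J - 4(A+Rd)| below this is treated as the singular denominator.
_SINGULAR_TOL = 1e-12


class QCReason(str, Enum):
    """Why a variable-J estimate passed or failed quality control."""

    OK = "ok"
    BELOW_10 = "below_10"
    ABOVE_50 = "above_50"
    SINGULAR = "singular"
    NONPOSITIVE_GM = "nonpositive_gm"


@dataclass(frozen=True)
class GmEstimate:
    """Per-record variable-J result.

    ``qc_pass`` is True iff 10 < δCc/δA < 50 (strict) and gm is finite
    and positive.
    """

    gm: float
    cc: float
    dCc_dA: float
    qc_pass: bool
    reason: QCReason


def j_nonphotorespiratory(A: float, Rd: float) -> float:
    """Electron transport under non-photorespiratory (1% O2) conditions.

    With photorespiration suppressed, J is fixed by gross assimilation:
    J = 4 (A + Rd).  A may be negative in darkness.
    """
    return 4.0 * (A + Rd)


def j_from_fluorescence(
    phi_PSII: float,
    PAR: float,
    absorptance: float = ABSORPTANCE_DEFAULT,
    beta: float = BETA_DEFAULT,
) -> float:
    """Electron transport from the PSII operating efficiency.

    J = ΦPSII · PAR · absorptance · β.
    """
    if not 0.0 <= phi_PSII <= 1.0:
        raise ValueError(f"phi_PSII={phi_PSII} outside [0, 1]")
    return phi_PSII * PAR * absorptance * beta


def gm_variable_j(
    A: float, ci: float, J: float, Rd: float, ci_star: float
) -> GmEstimate:
    """Invert the RuBP-limited FvCB equation for one record's gm.

    Returns a :class:`GmEstimate` with the δCc/δA reliability statistic
    and QC outcome.  A singular electron-transport denominator
    (J = 4(A+Rd)) or a non-positive/infinite gm never raises: the record
    is returned flagged so batch processing retains it.
    """
    for name, v in (("A", A), ("ci", ci), ("J", J), ("Rd", Rd), ("ci_star", ci_star)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")
    denom_j = J - 4.0 * (A + Rd)
    if abs(denom_j) < _SINGULAR_TOL:
        return GmEstimate(
            gm=math.nan, cc=math.nan, dCc_dA=math.inf,
            qc_pass=False, reason=QCReason.SINGULAR,
        )
    dcc_da = 12.0 * ci_star * J / denom_j**2
    cc = ci_star * (J + 8.0 * (A + Rd)) / denom_j
    drawdown = ci - cc  # = A/gm
    gm = A / drawdown if drawdown != 0.0 else math.inf
    in_window = DCC_DA_LOW < dcc_da < DCC_DA_HIGH
    gm_ok = math.isfinite(gm) and gm > 0.0
    if in_window and gm_ok:
        return GmEstimate(gm=gm, cc=cc, dCc_dA=dcc_da, qc_pass=True, reason=QCReason.OK)
    if not in_window:
        reason = QCReason.BELOW_10 if dcc_da <= DCC_DA_LOW else QCReason.ABOVE_50
    else:
        reason = QCReason.NONPOSITIVE_GM
    return GmEstimate(gm=gm, cc=cc, dCc_dA=dcc_da, qc_pass=False, reason=reason)


def cc_from_gm(ci: float, A: float, gm: float) -> float:
    """Chloroplastic CO2 from the mesophyll drawdown: cc = ci - A/gm."""
    if not gm > 0:
        raise ValueError(f"gm must be > 0, got {gm}")
    return ci - A / gm


def estimate_gm_batch(
    df: pd.DataFrame,
    ci_star: float,
    Rd: float,
    j_column: str | None = None,
    absorptance: float = ABSORPTANCE_DEFAULT,
    beta: float = BETA_DEFAULT,
) -> pd.DataFrame:
    """Variable-J gm for every row of a gas-exchange table.

    ``df`` needs columns A and ci, plus either ``j_column`` holding J
    directly or phi_PSII and PAR for the fluorescence route.  Returns a
    copy with gm, cc, dCc_dA, qc_pass and reason columns appended; rows
    are never dropped.  The δCc/δA filter is a pure per-row predicate, so
    the result is independent of row order and of re-application.
    """
    out = df.copy()
    if j_column is not None:
        J_values = df[j_column].astype(float)
    else:
        J_values = [
            j_from_fluorescence(p, q, absorptance, beta)
            for p, q in zip(df["phi_PSII"], df["PAR"])
        ]
    rows = [
        gm_variable_j(a, ci, j, Rd, ci_star)
        for a, ci, j in zip(df["A"].astype(float), df["ci"].astype(float), J_values)
    ]
    out["gm"] = [r.gm for r in rows]
    out["cc"] = [r.cc for r in rows]
    out["dCc_dA"] = [r.dCc_dA for r in rows]
    out["qc_pass"] = [r.qc_pass for r in rows]
    out["reason"] = [r.reason.value for r in rows]
    return out
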