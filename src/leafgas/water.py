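"""Leaf water relations: minimum conductance, RWC, chamber leak correction.

The minimum (cuticular) conductance gmin of a detached leaf is obtained
from its drying curve after stomatal closure.  Mass loss is linear in
time once stomata are shut, and the molar water flux per area divided by
the mole-fraction vapour gradient gives the conductance:

    gmin = (rate / M_water) / (area · VPD/Patm)

with rate the OLS mass-loss slope (g s⁻¹), M_water = 18.015 g mol⁻¹,
area the mean single-sided projected leaf area (m²) of the initial and
final photographs, and VPD/Patm the mole-fraction vapour pressure
deficit of the drying environment.  gmin is reported in mmol m⁻² s⁻¹.

Relative water content is RWC = 100 (FW − DW)/(SW − DW).

Chamber CO2 leaks are modelled as k·ΔC with k a diffusion coefficient
(mol s⁻¹) and ΔC the ambient-to-chamber CO2 mole-fraction gradient; k is
estimated from darkened-leaf measurements where respiration is constant,
so the apparent flux is linear in the imposed gradient and its OLS slope
is k.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .records import GasExchangeRecord

__all__ = [
    "M_WATER",
    "Environment",
    "DryingCurve",
    "GminModel",
    "GminResult",
    "rwc",
    "buck_saturation_vp",
    "vpd_mole_fraction",
    "estimate_leak_coefficient",
    "apply_leak_correction",
    "DegenerateDesignError",
]

#: Molar mass of water, g mol⁻¹.
M_WATER = 18.015


class DegenerateDesignError(ValueError):
    """The design carries no information (e.g. zero gradient spread)."""


def buck_saturation_vp(T: float) -> float:
    """Saturation vapour pressure over water (kPa) at T °C, Arden Buck form.

    es(T) = 0.61121 · exp[(18.678 − T/234.5) · T/(257.14 + T)].
    """
    return 0.61121 * math.exp((18.678 - T / 234.5) * (T / (257.14 + T)))


@dataclass(frozen=True)
class Environment:
    """Drying-bench air state: temperature (°C), RH (%), pressure (kPa)."""

    T: float = 20.0
    RH: float = 50.0
    Patm: float = 101.325


def vpd_mole_fraction(env: Environment) -> float:
    """Mole-fraction vapour pressure deficit VPD/Patm (mol mol⁻¹)."""
    vpd_kpa = buck_saturation_vp(env.T) * (1.0 - env.RH / 100.0)
    return vpd_kpa / env.Patm


def rwc(FW: float, DW: float, SW: float) -> float:
    """Relative water content, %: 100 (FW − DW)/(SW − DW).

    FW, DW, SW are the fresh, oven-dry and water-saturated leaf masses
    (g).  Values outside [0, 100] are returned but warned about, since
    they indicate a weighing or labelling problem.
    """
    if SW <= DW:
        raise ValueError(f"SW={SW} must exceed DW={DW}")
    if FW < 0:
        raise ValueError("FW must be >= 0")
    value = 100.0 * (FW - DW) / (SW - DW)
    if not 0.0 <= value <= 100.0:
        warnings.warn(f"RWC={value:.2f}% outside [0, 100]", stacklevel=2)
    return value


@dataclass
class DryingCurve:
    """Detached-leaf drying series: post-closure masses over time.

    ``times`` in seconds (strictly increasing, 0 = first post-closure
    weighing), ``masses`` in g, areas in m² (single-sided projected,
    before and after drying).
    """

    times: np.ndarray
    masses: np.ndarray
    area_initial: float
    area_final: float
    env: Environment

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.times.shape != self.masses.shape:
            raise ValueError("times and masses must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.area_initial <= 0 or self.area_final <= 0:
            raise ValueError("leaf areas must be > 0")


@dataclass
class GminResult:
    """Minimum-conductance estimate from one drying curve."""

    gmin: float  # mmol m⁻² s⁻¹
    mass_loss_rate: float  # g s⁻¹
    vpd_mole_fraction: float  # mol mol⁻¹
    r2: float
    n_points: int
    no_loss: bool = False

    def summary(self) -> str:
        lines = [
            f"Drying-curve gmin fit (n={self.n_points})",
            "=" * 40,
            f"gmin          : {self.gmin:9.4f} mmol m-2 s-1",
            f"mass-loss rate: {self.mass_loss_rate:9.3e} g s-1",
            f"VPD/Patm      : {self.vpd_mole_fraction:9.6f} mol mol-1",
            f"r2            : {self.r2:9.6f}",
        ]
        if self.no_loss:
            lines.append("flag: non-negative mass slope, gmin set to 0")
        return "\n".join(lines)


class GminModel:
    """OLS drying-curve fit for the minimum conductance.

    ``discard_s`` drops an initial settling interval (e.g. if weighing
    began before full stomatal closure); the default assumes the series
    already starts post-closure.
    """

    def __init__(self, curve: DryingCurve, discard_s: float = 0.0):
        mask = curve.times >= discard_s
        self.times = curve.times[mask]
        self.masses = curve.masses[mask]
        if self.times.size < 4:
            raise ValueError("need >= 4 post-closure points")
        self.curve = curve

    def fit(self) -> GminResult:
        X = sm.add_constant(self.times)
        res = sm.OLS(self.masses, X).fit()
        slope = float(res.params[1])
        vpd_frac = vpd_mole_fraction(self.curve.env)
        area = 0.5 * (self.curve.area_initial + self.curve.area_final)
        # -1e-15 g/s is far below any measurable loss; treats the exact-
        # constant series (slope at the floating floor) as no loss
        if slope >= -1e-15:
            return GminResult(
                gmin=0.0, mass_loss_rate=slope, vpd_mole_fraction=vpd_frac,
                r2=float(res.rsquared), n_points=self.times.size, no_loss=True,
            )
        rate = -slope  # g s⁻¹ lost
        gmin_mol = (rate / M_WATER) / (area * vpd_frac)
        return GminResult(
            gmin=1e3 * gmin_mol, mass_loss_rate=rate, vpd_mole_fraction=vpd_frac,
            r2=float(res.rsquared), n_points=self.times.size,
        )


def estimate_leak_coefficient(gradients, fluxes) -> float:
    """Chamber diffusion coefficient k (mol s⁻¹) from a darkened-leaf series.

    ``gradients`` are ambient-minus-chamber CO2 mole fractions
    (µmol mol⁻¹) and ``fluxes`` the apparent CO2 fluxes (µmol s⁻¹)
    recorded at each gradient.  With respiration constant in darkness,
    the flux is affine in the gradient and the OLS slope is k.
    """
    g = np.asarray(gradients, dtype=float)
    f = np.asarray(fluxes, dtype=float)
    if g.size < 3:
        raise ValueError("need >= 3 gradient levels")
    if np.ptp(g) < 1e-9:
        raise DegenerateDesignError("gradient spread < 1e-9")
    return float(np.polyfit(g, f, 1)[0])


def apply_leak_correction(
    record: GasExchangeRecord, k: float, leaf_area: float
) -> GasExchangeRecord:
    """Remove the chamber-leak contribution from a record's assimilation.

    Subtracts k·(c_ambient − ca)/leaf_area (µmol m⁻² s⁻¹) from A, where
    ca is the chamber CO2.  Records without ambient CO2 are returned
    unchanged with a ``leak_uncorrected`` flag.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if leaf_area <= 0:
        raise ValueError("leaf_area must be > 0")
    if record.c_ambient is None:
        warnings.warn("record has no ambient CO2; leak correction skipped", stacklevel=2)
        return record.with_(qc_flags=record.qc_flags + ("leak_uncorrected",))
    gradient = record.c_ambient - record.ca
    delta_A = k * gradient / leaf_area
    return record.with_(A=record.A - delta_A, leak_corrected=True)
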