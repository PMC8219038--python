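"""Farquhar–von Caemmerer–Berry (FvCB) biochemical photosynthesis model.

The forward model of C3 leaf carbon assimilation used throughout the
package, both to simulate gas-exchange observations with known truth and
as the demand function fitted to measured A–cc curves.  Net assimilation
is the minimum of the Rubisco-limited and RuBP-regeneration-limited
carboxylation rates minus day respiration:

    Ac = Vcmax (cc - Γ*) / (cc + Km)
    Aj = J (cc - Γ*) / (4 cc + 8 Γ*)
    A  = min(Ac, Aj) - Rd

with cc the chloroplastic CO2 mole fraction, Γ* the chloroplastic CO2
compensation point, Km = Kc (1 + O/Ko) the effective Michaelis constant
of Rubisco in the presence of oxygen, and J the electron transport rate.

All constants are at 25 °C; no temperature-response functions are applied
(measurements the package targets are made at 25 °C).  The branch
combination is a hard minimum: no triose-phosphate-use limitation and no
hyperbolic smoothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

from scipy.optimize import brentq

__all__ = [
    "KM_DEFAULT",
    "GAMMA_STAR_DEFAULT",
    "GS_CO2_RATIO",
    "Limitation",
    "FvCBParams",
    "OperatingPoint",
    "InvalidParameterError",
    "NoSolutionError",
    "km_chloroplastic",
    "electron_transport",
    "assimilation_demand",
    "total_co2_conductance",
    "solve_steady_state",
]

#: Default effective Michaelis constant Kc(1+O/Ko) at 25 °C, µmol mol⁻¹.
#: Shipped as a fixed constant for A–cc fitting; see docs/methods.md for
#: the provenance discussion (Bernacchi Kc/Ko with O=210 mmol mol⁻¹ gives
#: 617.33, slightly below this value).
KM_DEFAULT = 620.3322

#: Default chloroplastic CO2 compensation point at 25 °C, µmol mol⁻¹.
GAMMA_STAR_DEFAULT = 42.75

#: Ratio of H2O to CO2 diffusivity in air: gs(CO2) = gs(H2O)/1.6.
GS_CO2_RATIO = 1.6

# Residual tolerance of the supply-demand steady-state solver,
# µmol m⁻² s⁻¹.
SOLVER_TOL = 1e-9


class InvalidParameterError(ValueError):
    """A kinetic constant or conductance is outside its physical domain."""


class NoSolutionError(RuntimeError):
    """The coupled supply-demand system has no root in the search bracket."""


class Limitation(str, Enum):
    """Which FvCB branch sets the assimilation rate at an operating point."""

    RUBISCO = "rubisco"
    RUBP = "rubp"


@dataclass(frozen=True)
class FvCBParams:
    """Kinetic constants of the FvCB model at 25 °C.

    Parameters
    ----------
    Vcmax : float
        Maximum Rubisco carboxylation rate, µmol m⁻² s⁻¹.
    Jmax : float
        Maximum electron transport rate, µmol m⁻² s⁻¹.
    GammaStar : float
        Chloroplastic CO2 compensation point Γ*, µmol mol⁻¹.
    Km : float
        Effective Michaelis constant Kc(1+O/Ko), µmol mol⁻¹.  Recomputed
        from ``Kc``, ``Ko`` and ``O`` whenever all three are given.
    Kc, Ko, O : float or None
        Michaelis constants for CO2 (µmol mol⁻¹) and O2 (mmol mol⁻¹) and
        the oxygen mole fraction (mmol mol⁻¹); optional.
    Rd : float
        Day (non-photorespiratory) respiration, µmol m⁻² s⁻¹.
    theta_J : float
        Curvature of the J–PAR non-rectangular hyperbola, in (0, 1].
    phi_J : float
        Initial quantum yield of electron transport on an incident-PAR
        basis, in (0, 1).
    """

    Vcmax: float = 60.0
    Jmax: float = 120.0
    GammaStar: float = GAMMA_STAR_DEFAULT
    Km: float = KM_DEFAULT
    Kc: float | None = None
    Ko: float | None = None
    O: float | None = None
    Rd: float = 1.0
    theta_J: float = 0.7
    phi_J: float = 0.3

    def __post_init__(self) -> None:
        for name in ("Vcmax", "Jmax", "GammaStar", "Km", "Rd"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if not 0.0 < self.theta_J <= 1.0:
            raise InvalidParameterError("theta_J must be in (0, 1]")
        if not 0.0 < self.phi_J < 1.0:
            raise InvalidParameterError("phi_J must be in (0, 1)")
        if self.Kc is not None and self.Ko is not None and self.O is not None:
            object.__setattr__(
                self, "Km", km_chloroplastic(self.Kc, self.Ko, self.O)
            )

    def with_(self, **kwargs) -> "FvCBParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class OperatingPoint:
    """One steady-state solution of the coupled supply-demand system.

    ``GammaStar <= cc <= ci <= ca`` holds whenever ``A >= 0``; in darkness
    (A < 0) the CO2 gradient reverses and cc > ci > ca.
    """

    A: float  # net assimilation, µmol m⁻² s⁻¹
    ci: float  # intercellular CO2, µmol mol⁻¹
    cc: float  # chloroplastic CO2, µmol mol⁻¹
    limitation: Limitation
    residual: float = 0.0  # |supply - demand| at the solution


def km_chloroplastic(Kc: float, Ko: float, O: float) -> float:
    """Effective Michaelis constant Km = Kc (1 + O/Ko).

    Parameters are the Rubisco Michaelis constants for CO2 (``Kc``,
    µmol mol⁻¹) and O2 (``Ko``, mmol mol⁻¹) and the oxygen mole fraction
    ``O`` (mmol mol⁻¹).  The O/Ko ratio is dimensionless, so the result
    is in µmol mol⁻¹.
    """
    if Kc <= 0 or Ko <= 0:
        raise InvalidParameterError("Kc and Ko must be > 0")
    if O < 0:
        raise InvalidParameterError("O must be >= 0")
    return Kc * (1.0 + O / Ko)


def electron_transport(
    PAR: float,
    Jmax: float,
    theta_J: float = 0.7,
    phi_J: float = 0.3,
) -> float:
    """Electron transport rate J(PAR) from the non-rectangular hyperbola.

    Smaller root of ``theta_J J² - (phi_J PAR + Jmax) J + phi_J PAR Jmax = 0``,
    computed in the numerically stable 2c/(b+sqrt(disc)) form.  J(0)=0 and
    J -> Jmax as PAR -> ∞.
    """
    if not 0.0 < theta_J <= 1.0:
        raise InvalidParameterError("theta_J must be in (0, 1]")
    if PAR < 0:
        raise InvalidParameterError("PAR must be >= 0")
    b = phi_J * PAR + Jmax
    c = phi_J * PAR * Jmax
    disc = b * b - 4.0 * theta_J * c
    if disc < 0.0:  # roundoff only; theta<=1 guarantees disc>=0
        disc = 0.0
    return 2.0 * c / (b + math.sqrt(disc))


def assimilation_demand(
    cc: float, params: FvCBParams, J: float
) -> tuple[float, Limitation]:
    """Net assimilation demanded by the biochemistry at chloroplastic CO2 cc.

    Returns ``(A, limitation)`` where A = min(Ac, Aj) - Rd and the
    limitation flag records the smaller branch (ties go to Rubisco).
    """
    if cc < 0:
        raise InvalidParameterError("cc must be >= 0")
    if J < 0:
        raise InvalidParameterError("J must be >= 0")
    denom_c = cc + params.Km
    denom_j = 4.0 * cc + 8.0 * params.GammaStar
    if denom_c == 0.0 or denom_j == 0.0:
        raise ZeroDivisionError("singular FvCB branch denominator")
    Ac = params.Vcmax * (cc - params.GammaStar) / denom_c
    Aj = J * (cc - params.GammaStar) / denom_j
    if Ac <= Aj:
        return Ac - params.Rd, Limitation.RUBISCO
    return Aj - params.Rd, Limitation.RUBP


def total_co2_conductance(gs_w: float, gm: float) -> float:
    """Series CO2 conductance from ambient to chloroplast.

    ``1/g_tot = 1.6/gs_w + 1/gm`` with gs_w the stomatal conductance to
    water vapour and gm the mesophyll conductance to CO2.
    """
    if gs_w <= 0 or gm <= 0:
        raise InvalidParameterError("gs_w and gm must be > 0")
    return 1.0 / (GS_CO2_RATIO / gs_w + 1.0 / gm)


def solve_steady_state(
    ca: float,
    gs_w: float,
    gm: float,
    params: FvCBParams,
    PAR: float | None = None,
    J: float | None = None,
) -> OperatingPoint:
    """Solve the coupled CO2 supply-demand system for the operating point.

    Finds the operating point at which biochemical demand equals
    diffusive supply, ``A_demand(cc) = (ca - cc) g_tot``, then recovers
    ci = ca - 1.6 A / gs_w.  ``J`` may be given directly; otherwise it is
    computed from ``PAR`` via :func:`electron_transport`.

    The root is found in A rather than cc — the map
    ``h(A) = A_demand(ca - A/g_tot) - A`` is strictly decreasing and
    stays well-conditioned even as both conductances grow without bound
    (where cc pins to ca and a cc-space search would hit the floating
    floor).  The bracket [-Rd - 1, max(A_demand(ca), 0) + 1] provably
    contains the unique root when ca > Γ*, including dark/respiring
    states (A < 0, reversed gradient, cc > ca).

    Raises
    ------
    NoSolutionError
        If ca <= Γ* or the residual cannot be driven below 1e-9.
    """
    if J is None:
        if PAR is None:
            raise InvalidParameterError("provide PAR or J")
        J = electron_transport(PAR, params.Jmax, params.theta_J, params.phi_J)
    g_tot = total_co2_conductance(gs_w, gm)
    if ca <= params.GammaStar:
        raise NoSolutionError(
            f"ca={ca} <= GammaStar={params.GammaStar}: no steady state with "
            "positive assimilation exists"
        )

    def cc_of(A: float) -> float:
        # clamp for bracket endpoints only; the root itself has cc > 0
        return max(ca - A / g_tot, 0.0)

    def h(A: float) -> float:
        return assimilation_demand(cc_of(A), params, J)[0] - A

    lo = -params.Rd - 1.0
    hi = max(assimilation_demand(ca, params, J)[0], 0.0) + 1.0
    f_lo, f_hi = h(lo), h(hi)
    if f_lo < 0.0 or f_hi > 0.0:  # cannot occur for a valid demand function
        raise NoSolutionError(
            f"no sign change on A in [{lo}, {hi}] (h_lo={f_lo}, h_hi={f_hi})"
        )
    A = brentq(h, lo, hi, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    cc = cc_of(A)
    A_dem, limitation = assimilation_demand(cc, params, J)
    res = abs(A_dem - A)
    if res >= SOLVER_TOL:
        raise NoSolutionError(f"solver residual {res} exceeds {SOLVER_TOL}")
    ci = ca - GS_CO2_RATIO * A / gs_w
    return OperatingPoint(A=A, ci=ci, cc=cc, limitation=limitation, residual=res)
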