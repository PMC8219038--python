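"""Seeded generators for every input the pipeline consumes.

Each generator simulates one instrument protocol from a stated
generative model with known true parameters, so every estimator in the
package can be tested by parameter recovery without any external data:

* A–ci curves (17 CO2 steps, first at 400 µmol mol⁻¹) and light-response
  curves (9 descending PAR steps) from the coupled FvCB supply–demand
  solver;
* Laisk families: low-CO2 A–ci sub-curves at PAR {300, 150, 100, 50}
  with CO2 steps {150, 125, 100, 75, 50}, either from the full FvCB
  model or in an idealized exact-lines mode whose regression lines all
  pass through (ci*, −Rd) by construction;
* detached-leaf drying series, sealed-pot weight series, darkened-leaf
  chamber-leak series and stopped-flow fluorescence decay traces.

Noise is multiplicative Gaussian on the fluxes (A, gs) with a common
coefficient of variation — never on the set points (ca, PAR) — drawn
from a single seeded stream in record order, so a seed fixes the
dataset byte-for-byte.  Simulated PSII operating efficiency is inverted
from the generating electron flux, ΦPSII = J/(β·α·PAR) with β = 0.5,
α = 0.84, where J is the stoichiometric flux implied by the noise-free
(A + Rd) at the operating point — the quantity fluorescence actually
reports — not the NRH light-supply rate, which exceeds it whenever
Rubisco limits.

Internal consistency of the truth: the apparent (Laisk) compensation
point ci* and the chloroplastic Γ* differ by the mesophyll drawdown at
the compensation state, Γ* = ci* + Rd/gm.  :func:`make_truth` applies
this so that Laisk families generated from the FvCB model intersect at
the declared (ci*, −Rd).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fvcb import (
    FvCBParams,
    NoSolutionError,
    electron_transport,
    solve_steady_state,
)
from .mesophyll import ABSORPTANCE_DEFAULT, BETA_DEFAULT
from .records import GasExchangeRecord, ResponseCurve
from .transpiration import TranspirationSeries, cumulative_leaf_area
from .water import M_WATER, DryingCurve, Environment, vpd_mole_fraction

__all__ = [
    "ACI_CA_STEPS",
    "LIGHT_PAR_STEPS",
    "LAISK_PAR_LEVELS",
    "LAISK_CO2_STEPS",
    "NOISE_CV_DEFAULT",
    "BALANCE_NOISE_G",
    "SyntheticTruth",
    "make_truth",
    "generate_aci_curve",
    "generate_light_curve",
    "generate_laisk_family",
    "generate_drying_series",
    "generate_pot_weights",
    "generate_dark_leak_series",
    "add_chamber_leak",
    "generate_decay_trace",
    "generate_variable_j_records",
]

#: Full A–ci protocol: first measurement at growth CO2 (400), then the
#: ascending and descending step sequence; 17 steps in all.
ACI_CA_STEPS: tuple[float, ...] = (
    400, 450, 550, 650, 750, 850, 1000, 1500, 2000,
    400, 350, 300, 250, 200, 150, 100, 50,
)

#: Light-response protocol: descending irradiance to darkness.
LIGHT_PAR_STEPS: tuple[float, ...] = (2000, 1500, 1000, 500, 200, 100, 50, 20, 0)

#: Laisk protocol: sub-saturating irradiances and low-CO2 steps.
LAISK_PAR_LEVELS: tuple[float, ...] = (300, 150, 100, 50)
LAISK_CO2_STEPS: tuple[float, ...] = (150, 125, 100, 75, 50)

#: Default relative Gaussian noise on fluxes (A, gs).  The target
#: instruments do not publish a noise figure; 2% is a typical match-mode
#: repeatability for a well-calibrated open system.
NOISE_CV_DEFAULT = 0.02

#: Default balance noise for drying/pot weighings, g (0.5 mg analytical
#: balance for leaves is 0.0005; pot-scale weighings use 0.5).
BALANCE_NOISE_G = 0.0005
POT_BALANCE_NOISE_G = 0.5


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameter set attached to every generated dataset."""

    fvcb: FvCBParams
    gs_w: float = 0.3  # mol m⁻² s⁻¹, stomatal conductance to H2O
    gm_true: float = 0.2  # mol m⁻² s⁻¹, mesophyll conductance to CO2
    ci_star: float = 38.95  # µmol mol⁻¹, apparent compensation point
    noise_cv: float = NOISE_CV_DEFAULT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.gm_true <= 0 or self.gs_w <= 0:
            raise ValueError("conductances must be > 0")


def make_truth(
    Vcmax: float = 60.0,
    Jmax: float = 120.0,
    Rd: float = 0.914,
    ci_star: float = 38.95,
    gs_w: float = 0.3,
    gm_true: float = 0.2,
    noise_cv: float = NOISE_CV_DEFAULT,
    seed: int = 0,
    theta_J: float = 0.7,
    phi_J: float = 0.3,
    Km: float | None = None,
) -> SyntheticTruth:
    """Build a self-consistent truth with Γ* = ci* + Rd/gm.

    Defaults are field-typical for well-watered Arabidopsis at 25 °C;
    Rd and ci* default to the package's global-average constants.
    """
    from .fvcb import KM_DEFAULT

    gamma_star = ci_star + Rd / gm_true
    params = FvCBParams(
        Vcmax=Vcmax, Jmax=Jmax, GammaStar=gamma_star,
        Km=KM_DEFAULT if Km is None else Km,
        Rd=Rd, theta_J=theta_J, phi_J=phi_J,
    )
    return SyntheticTruth(
        fvcb=params, gs_w=gs_w, gm_true=gm_true, ci_star=ci_star,
        noise_cv=noise_cv, seed=seed,
    )


def _phi_psii(J: float, PAR: float) -> float:
    """Invert the fluorescence J route for the simulated ΦPSII."""
    if PAR <= 0:
        return 0.8  # dark Fv'/Fm'-like value; yields J = 0 either way
    return J / (BETA_DEFAULT * ABSORPTANCE_DEFAULT * PAR)


def _stoichiometric_j(A: float, cc: float, params: FvCBParams) -> float:
    """Electron flux implied by (A+Rd) at the operating point.

    Chlorophyll fluorescence reports the actual linear electron flux,
    which in steady state satisfies J = (A+Rd)(4cc+8Γ*)/(cc−Γ*)
    whichever process limits carboxylation: under Rubisco limitation
    PSII down-regulates below the light-supply (NRH) J.  At cc = Γ* the
    ratio is indeterminate (A = −Rd); the light-supply J is the sensible
    value there.
    """
    if abs(cc - params.GammaStar) < 1e-9:
        return math.nan  # caller substitutes the light-supply J
    return (A + params.Rd) * (4.0 * cc + 8.0 * params.GammaStar) / (cc - params.GammaStar)


def _simulate_record(
    truth: SyntheticTruth,
    ca: float,
    PAR: float,
    rng: np.random.Generator,
    flow: float,
) -> GasExchangeRecord:
    """One steady-state record with flux noise; failures come back flagged."""
    J = electron_transport(PAR, truth.fvcb.Jmax, truth.fvcb.theta_J, truth.fvcb.phi_J)
    try:
        op = solve_steady_state(ca, truth.gs_w, truth.gm_true, truth.fvcb, J=J)
    except NoSolutionError:
        # draw the noise anyway so the stream stays aligned record-by-record
        rng.standard_normal(2)
        return GasExchangeRecord(
            A=math.nan, gs_w=truth.gs_w, ci=math.nan, ca=ca, PAR=PAR,
            flow=flow, phi_PSII=_phi_psii(J, PAR),
            qc_flags=("no_steady_state",),
        )
    z = rng.standard_normal(2)
    A_obs = op.A * (1.0 + truth.noise_cv * z[0])
    gs_obs = truth.gs_w * (1.0 + truth.noise_cv * z[1])
    ci_obs = ca - 1.6 * A_obs / gs_obs
    J_fluor = _stoichiometric_j(op.A, op.cc, truth.fvcb)
    if math.isnan(J_fluor):
        J_fluor = J
    return GasExchangeRecord(
        A=A_obs, gs_w=gs_obs, ci=ci_obs, ca=ca, PAR=PAR, flow=flow,
        phi_PSII=_phi_psii(J_fluor, PAR),
    )


def generate_aci_curve(
    truth: SyntheticTruth,
    ca_steps: tuple[float, ...] | None = None,
    seed: int | None = None,
    PAR: float = 1500.0,
) -> ResponseCurve:
    """Simulate a full A–ci curve at constant saturating PAR."""
    steps = ACI_CA_STEPS if ca_steps is None else tuple(ca_steps)
    if any(s <= 0 for s in steps):
        raise ValueError("all ca steps must be > 0")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    records = [_simulate_record(truth, ca, PAR, rng, flow=300.0) for ca in steps]
    return ResponseCurve(
        curve_type="aci", records=records,
        metadata={"PAR": PAR, "protocol": "aci"}, truth=truth,
    )


def generate_light_curve(
    truth: SyntheticTruth,
    par_steps: tuple[float, ...] | None = None,
    seed: int | None = None,
    ca: float = 400.0,
    nrh_truth: tuple[float, float, float, float] | None = None,
) -> ResponseCurve:
    """Simulate a light-response curve at constant ca.

    By default A(I) comes from the full FvCB steady-state solver.  With
    ``nrh_truth = (phi, Asat, theta, Rd)`` the curve is generated from
    the non-rectangular hyperbola itself (stomata held at the truth's
    gs), giving an exact target for NRH round-trip tests.  In either
    mode the simulated ΦPSII is consistent with the generating J
    (non-photorespiratory J = 4(A+Rd) in NRH mode, matching the 1%-O2
    protocol these curves emulate).
    """
    steps = LIGHT_PAR_STEPS if par_steps is None else tuple(par_steps)
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    records = []
    if nrh_truth is not None:
        from .fitting import nrh_net_assimilation

        phi, asat, theta, rd = nrh_truth
        for par in steps:
            A_true = float(nrh_net_assimilation(par, phi, asat, theta, rd))
            z = rng.standard_normal(2)
            A_obs = A_true * (1.0 + truth.noise_cv * z[0])
            gs_obs = truth.gs_w * (1.0 + truth.noise_cv * z[1])
            J = 4.0 * (A_true + rd)
            records.append(
                GasExchangeRecord(
                    A=A_obs, gs_w=gs_obs, ci=ca - 1.6 * A_obs / gs_obs,
                    ca=ca, PAR=par, flow=300.0, phi_PSII=_phi_psii(J, par),
                )
            )
    else:
        records = [_simulate_record(truth, ca, par, rng, flow=300.0) for par in steps]
    return ResponseCurve(
        curve_type="light", records=records,
        metadata={"ca": ca, "protocol": "light"}, truth=truth,
    )


def generate_laisk_family(
    truth: SyntheticTruth,
    par_levels: tuple[float, ...] | None = None,
    co2_steps: tuple[float, ...] | None = None,
    seed: int | None = None,
    idealized: bool = False,
) -> list[ResponseCurve]:
    """Simulate a family of low-CO2 A–ci sub-curves for the Laisk method.

    In ``idealized`` mode each sub-curve is an exact line through
    (ci*, −Rd) with a PAR-dependent slope, separating estimator
    correctness from FvCB curvature; otherwise sub-curves come from the
    full model, which is near-linear below 150 µmol mol⁻¹.
    """
    pars = LAISK_PAR_LEVELS if par_levels is None else tuple(par_levels)
    cas = LAISK_CO2_STEPS if co2_steps is None else tuple(co2_steps)
    if len(pars) < 2 or len(cas) < 2:
        raise ValueError("need >= 2 PAR levels and >= 2 CO2 steps")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    family = []
    for par in pars:
        records = []
        if idealized:
            J = electron_transport(
                par, truth.fvcb.Jmax, truth.fvcb.theta_J, truth.fvcb.phi_J
            )
            slope = J / (4.0 * truth.ci_star + 8.0 * truth.fvcb.GammaStar)
            for ca in cas:
                ci = float(ca)
                A_true = slope * (ci - truth.ci_star) - truth.fvcb.Rd
                z = rng.standard_normal(2)
                A_obs = A_true * (1.0 + truth.noise_cv * z[0])
                gs_obs = truth.gs_w * (1.0 + truth.noise_cv * z[1])
                records.append(
                    GasExchangeRecord(
                        A=A_obs, gs_w=gs_obs, ci=ci, ca=ci, PAR=par,
                        flow=200.0, phi_PSII=_phi_psii(J, par),
                    )
                )
        else:
            records = [_simulate_record(truth, ca, par, rng, flow=200.0) for ca in cas]
        family.append(
            ResponseCurve(
                curve_type="laisk", records=records,
                metadata={"PAR": par, "protocol": "laisk", "idealized": idealized},
                truth=truth,
            )
        )
    return family


def generate_drying_series(
    gmin_true: float = 0.008,
    area: float = 4e-4,
    env: Environment | None = None,
    schedule: np.ndarray | None = None,
    seed: int = 0,
    m0: float = 0.10,
    noise_g: float = BALANCE_NOISE_G,
) -> DryingCurve:
    """Simulate a detached-leaf drying curve after stomatal closure.

    mass(t) = m0 − r t + ε with r = gmin · (VPD/Patm) · area · M_water,
    gmin in mol m⁻² s⁻¹, area in m² (single-sided) and ε balance noise.
    The default schedule is 8 weighings 27 min apart over ~3.2 h.
    """
    if gmin_true < 0:
        raise ValueError("gmin_true must be >= 0")
    env = Environment() if env is None else env
    t = np.arange(8) * 1620.0 if schedule is None else np.asarray(schedule, float)
    rng = np.random.default_rng(seed)
    rate = gmin_true * vpd_mole_fraction(env) * area * M_WATER  # g s⁻¹
    masses = m0 - rate * t + noise_g * rng.standard_normal(t.size)
    return DryingCurve(
        times=t, masses=masses, area_initial=area, area_final=area, env=env,
    )


def generate_pot_weights(
    E_true: float = 2500.0,
    leaf_areas: list[tuple[float, float]] | None = None,
    waterings: list[tuple[float, float]] | None = None,
    seed: int = 0,
    Wi: float = 600.0,
    FW: float = 30.0,
    noise_g: float = POT_BALANCE_NOISE_G,
    mode: str = "integral",
) -> TranspirationSeries:
    """Simulate a sealed-pot gravimetric series consistent with E_true.

    The final weight is Wf = Wi + ΣV − FW − E_true·At (plus balance
    noise), with At the cumulative leaf area under the same convention
    the estimator uses (``mode``).  Watering volumes are credited to the
    running water budget on their day, as in the protocol.
    """
    if leaf_areas is None:
        leaf_areas = [(0.0, 2.0), (7.0, 12.0), (14.0, 30.0), (21.0, 60.0), (30.0, 90.0)]
    if waterings is None:
        waterings = [(2.0, 20.0), (6.0, 25.0), (10.0, 25.0), (14.0, 30.0),
                     (18.0, 30.0), (22.0, 35.0), (26.0, 35.0)]
    rng = np.random.default_rng(seed)
    probe = TranspirationSeries(
        Wi=Wi, Wf=Wi, FW=FW, waterings=list(waterings),
        leaf_areas=list(leaf_areas), duration=30.0,
    )
    at = cumulative_leaf_area(probe, mode=mode)
    total_v = probe.total_water_added
    wf = Wi + total_v - FW - E_true * at + noise_g * rng.standard_normal()
    return TranspirationSeries(
        Wi=Wi, Wf=wf, FW=FW, waterings=list(waterings),
        leaf_areas=list(leaf_areas), duration=30.0,
    )


def generate_dark_leak_series(
    k_true: float = 0.40,
    gradients: tuple[float, ...] = (-20.0, -10.0, 0.0, 10.0, 20.0),
    resp_flux: float = -0.5,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Darkened-leaf leak series: apparent flux = resp + k·gradient + ε.

    ``gradients`` are ambient-minus-chamber CO2 mole fractions
    (µmol mol⁻¹); ``resp_flux`` the constant dark respiration signal
    (µmol s⁻¹).  Returns (gradients, fluxes).
    """
    g = np.asarray(gradients, dtype=float)
    rng = np.random.default_rng(seed)
    f = resp_flux + k_true * g + noise * rng.standard_normal(g.size)
    return g, f


def add_chamber_leak(
    curve: ResponseCurve, k: float, leaf_area: float, c_ambient: float = 420.0
) -> ResponseCurve:
    """Perturb a curve's fluxes with a chamber leak of coefficient k.

    The inverse of the leak correction: each record gains
    k·(c_ambient − ca)/leaf_area on A and has its ambient CO2 recorded,
    so correcting with the estimated k restores the original fluxes.
    """
    records = [
        r.with_(A=r.A + k * (c_ambient - r.ca) / leaf_area, c_ambient=c_ambient)
        for r in curve.records
    ]
    return ResponseCurve(
        curve_type=curve.curve_type, records=records,
        metadata={**curve.metadata, "leak_k": k, "leaf_area": leaf_area},
        truth=curve.truth,
    )


def generate_decay_trace(
    k_true: float = 250.0,
    amplitude: float = 1.5,
    plateau: float = 0.5,
    dt: float = 0.000125,
    duration: float = 0.008,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stopped-flow fluorescence trace F(t) = A e^{−kt} + plateau + ε.

    Sampled every ``dt`` seconds (default 0.125 ms) over ``duration``
    (default 8 ms); ``noise_frac`` scales Gaussian noise by the
    amplitude.  Returns (t, F).
    """
    t = np.arange(0.0, duration + dt / 2, dt)
    rng = np.random.default_rng(seed)
    F = amplitude * np.exp(-k_true * t) + plateau
    if noise_frac > 0:
        F = F + noise_frac * amplitude * rng.standard_normal(t.size)
    return t, F


def generate_variable_j_records(
    gm_values,
    ca_values,
    gs_w: float = 0.3,
    PAR: float = 1000.0,
    params: FvCBParams | None = None,
) -> pd.DataFrame:
    """Noise-free RuBP-limited records over a gm × ca grid.

    Built for variable-J recovery tests: a high Vcmax keeps every point
    electron-transport-limited, so the variable-J inversion (with ci*
    set to the simulation's Γ*) must return the generating gm exactly.
    Raises if any grid point turns out Rubisco-limited.
    """
    if params is None:
        params = FvCBParams(Vcmax=150.0, Jmax=120.0, Rd=1.0)
    J = electron_transport(PAR, params.Jmax, params.theta_J, params.phi_J)
    rows = []
    for gm in np.asarray(gm_values, dtype=float):
        for ca in np.asarray(ca_values, dtype=float):
            op = solve_steady_state(ca, gs_w, gm, params, J=J)
            if op.limitation.value != "rubp":
                raise ValueError(
                    f"grid point ca={ca}, gm={gm} is not RuBP-limited"
                )
            rows.append(
                {"A": op.A, "ci": op.ci, "cc": op.cc, "J": J,
                 "Rd": params.Rd, "GammaStar": params.GammaStar,
                 "gm_true": gm, "ca": ca}
            )
    return pd.DataFrame(rows)
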