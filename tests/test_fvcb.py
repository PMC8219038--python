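"""FvCB forward model: kinetics, electron transport, steady-state solver."""

import math

import numpy as np
import pytest

from leafgas.fvcb import (
    GS_CO2_RATIO,
    FvCBParams,
    InvalidParameterError,
    Limitation,
    NoSolutionError,
    assimilation_demand,
    electron_transport,
    km_chloroplastic,
    solve_steady_state,
    total_co2_conductance,
)


class TestKmChloroplastic:
    @pytest.mark.parametrize(
        "kc,ko,o,expected",
        [
            (272.38, 165.82, 0.0, 272.38),  # no oxygen collapses to Kc
            (272.38, 165.82, 210.0, 272.38 * (1 + 210.0 / 165.82)),
        ],
    )
    def test_closed_form(self, kc, ko, o, expected):
        assert km_chloroplastic(kc, ko, o) == pytest.approx(expected, rel=1e-12)

    def test_hand_value_with_ambient_oxygen(self):
        assert km_chloroplastic(272.38, 165.82, 210.0) == pytest.approx(617.33, abs=0.01)

    @pytest.mark.parametrize("kc,ko", [(0.0, 165.82), (272.38, 0.0), (-1.0, 1.0)])
    def test_nonpositive_constants_rejected(self, kc, ko):
        with pytest.raises(InvalidParameterError):
            km_chloroplastic(kc, ko, 210.0)

    def test_params_rederive_km_from_kinetics(self):
        p = FvCBParams(Kc=272.38, Ko=165.82, O=210.0)
        assert p.Km == pytest.approx(617.331, abs=1e-2)


class TestAssimilationDemand:
    def test_compensation_point_returns_minus_rd(self):
        p = FvCBParams(Vcmax=60, GammaStar=40, Km=620, Rd=1.37)
        for J in (0.0, 50.0, 1e6):
            A, _ = assimilation_demand(40.0, p, J)
            assert A == pytest.approx(-1.37, abs=1e-12)

    def test_rubisco_branch_hand_value(self):
        p = FvCBParams(Vcmax=60, GammaStar=40, Km=620, Rd=1)
        A, lim = assimilation_demand(300.0, p, 1e6)
        assert A == pytest.approx(60 * 260 / 920 - 1, rel=1e-12)  # 15.9565
        assert lim is Limitation.RUBISCO

    def test_rubp_branch_hand_value(self):
        p = FvCBParams(Vcmax=1e5, GammaStar=40, Rd=1)
        A, lim = assimilation_demand(300.0, p, 120.0)
        assert A == pytest.approx(120 * 260 / 1520 - 1, rel=1e-12)  # 19.526
        assert lim is Limitation.RUBP

    def test_continuous_at_branch_crossover(self):
        p = FvCBParams(Vcmax=60, GammaStar=40, Km=620, Rd=1)
        J = 103.0
        # crossover cc where Ac == Aj
        cc_x = (J * p.Km - 8 * p.GammaStar * p.Vcmax) / (4 * p.Vcmax - J)
        below, _ = assimilation_demand(cc_x - 1e-9, p, J)
        above, _ = assimilation_demand(cc_x + 1e-9, p, J)
        assert abs(above - below) < 1e-9


class TestElectronTransport:
    def test_dark_is_zero(self):
        assert electron_transport(0.0, 150.0) == 0.0

    def test_saturates_at_jmax(self):
        assert electron_transport(1e9, 150.0, 0.7, 0.3) == pytest.approx(150.0, rel=1e-3)
        assert electron_transport(2000.0, 150.0) < 150.0

    def test_matches_quadratic_formula_oracle(self):
        jmax, phi, theta, par = 150.0, 0.3, 0.7, 1000.0
        b = phi * par + jmax
        root = (b - math.sqrt(b * b - 4 * theta * phi * par * jmax)) / (2 * theta)
        assert electron_transport(par, jmax, theta, phi) == pytest.approx(root, rel=1e-12)

    def test_invalid_theta_rejected(self):
        with pytest.raises(InvalidParameterError):
            electron_transport(500.0, 150.0, theta_J=1.5)


class TestSteadyState:
    def test_infinite_conductances_remove_drawdown(self):
        p = FvCBParams(Vcmax=60, GammaStar=40, Km=620, Rd=1)
        op = solve_steady_state(400.0, 1e9, 1e9, p, J=1e6)
        A_direct, _ = assimilation_demand(400.0, p, 1e6)
        assert op.cc == pytest.approx(400.0, abs=1e-4)
        assert op.ci == pytest.approx(400.0, abs=1e-4)
        assert op.A == pytest.approx(A_direct, abs=1e-4)

    def test_hand_example_rubisco_limited(self):
        p = FvCBParams(Vcmax=60, GammaStar=40, Km=620, Rd=1)
        op = solve_steady_state(400.0, 0.30, 0.20, p, J=1e6)
        assert op.limitation is Limitation.RUBISCO
        assert op.A == pytest.approx(13.84, abs=0.01)
        assert op.ci == pytest.approx(326.2, abs=0.1)
        assert op.cc == pytest.approx(257.0, abs=0.1)

    def test_drawdown_identity_ci_minus_cc(self):
        p = FvCBParams()
        for gm in (0.05, 0.2, 0.5):
            op = solve_steady_state(400.0, 0.3, gm, p, PAR=1000.0)
            assert op.ci - op.cc == pytest.approx(op.A / gm, abs=1e-9)

    def test_agrees_with_bisection_oracle(self):
        p = FvCBParams(Vcmax=60, GammaStar=40, Km=620, Rd=1)
        ca, gs_w, gm, J = 400.0, 0.30, 0.20, 1e6
        g_tot = total_co2_conductance(gs_w, gm)

        lo, hi = p.GammaStar, ca
        for _ in range(60):  # plain bisection on the residual
            mid = 0.5 * (lo + hi)
            if assimilation_demand(mid, p, J)[0] - (ca - mid) * g_tot < 0:
                lo = mid
            else:
                hi = mid
        op = solve_steady_state(ca, gs_w, gm, p, J=J)
        assert op.cc == pytest.approx(0.5 * (lo + hi), abs=1e-8)

    def test_monotone_in_both_conductances(self):
        p = FvCBParams()
        grid = [0.05, 0.1, 0.2, 0.4, 0.8]
        a_gm = [solve_steady_state(400.0, 0.3, g, p, PAR=1200.0).A for g in grid]
        a_gs = [solve_steady_state(400.0, g, 0.2, p, PAR=1200.0).A for g in grid]
        assert np.all(np.diff(a_gm) > 0)
        assert np.all(np.diff(a_gs) > 0)

    def test_residual_below_tolerance(self):
        p = FvCBParams()
        op = solve_steady_state(400.0, 0.3, 0.2, p, PAR=800.0)
        assert op.residual < 1e-9

    def test_darkness_gives_respiration_and_reversed_gradient(self):
        p = FvCBParams(Rd=0.914)
        op = solve_steady_state(400.0, 0.3, 0.2, p, J=0.0)
        assert op.A == pytest.approx(-0.914, abs=1e-9)
        assert op.cc > op.ci > 400.0

    def test_ca_below_gamma_star_errors(self):
        p = FvCBParams(GammaStar=42.75)
        with pytest.raises(NoSolutionError):
            solve_steady_state(40.0, 0.3, 0.2, p, PAR=500.0)

    def test_ordering_invariant_when_assimilating(self):
        p = FvCBParams()
        op = solve_steady_state(400.0, 0.3, 0.2, p, PAR=1500.0)
        assert p.GammaStar <= op.cc <= op.ci <= 400.0
        assert op.ci == pytest.approx(400.0 - GS_CO2_RATIO * op.A / 0.3, abs=1e-9)


class TestParamValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            FvCBParams(Vcmax=-5)

    @pytest.mark.parametrize("field,value", [("theta_J", 0.0), ("theta_J", 1.2),
                                             ("phi_J", 0.0), ("phi_J", 1.0)])
    def test_quantum_yield_and_curvature_domains(self, field, value):
        with pytest.raises(InvalidParameterError):
            FvCBParams(**{field: value})
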