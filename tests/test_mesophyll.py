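"""Variable-J mesophyll conductance and the δCc/δA reliability filter."""

import math

import numpy as np
import pandas as pd
import pytest

from leafgas import synthetic as syn
from leafgas.fvcb import FvCBParams, electron_transport, solve_steady_state
from leafgas.mesophyll import (
    QCReason,
    cc_from_gm,
    estimate_gm_batch,
    gm_variable_j,
    j_from_fluorescence,
    j_nonphotorespiratory,
)


class TestJRoutes:
    @pytest.mark.parametrize("a,rd,expected", [(10, 1, 44), (-1.0, 1.0, 0.0), (0, 0, 0)])
    def test_nonphotorespiratory_stoichiometry(self, a, rd, expected):
        assert j_nonphotorespiratory(a, rd) == pytest.approx(expected)

    def test_fluorescence_route_hand_value(self):
        assert j_from_fluorescence(0.25, 1000.0, 0.84, 0.5) == pytest.approx(105.0)

    def test_fluorescence_dark(self):
        assert j_from_fluorescence(0.0, 1500.0) == 0.0

    def test_phi_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            j_from_fluorescence(1.2, 500.0)

    def test_round_trip_with_simulated_phi_psii(self, noise_free_truth):
        curve = syn.generate_aci_curve(noise_free_truth)
        p = noise_free_truth.fvcb
        for r in curve.records:
            op = solve_steady_state(
                r.ca, noise_free_truth.gs_w, noise_free_truth.gm_true, p,
                J=electron_transport(r.PAR, p.Jmax, p.theta_J, p.phi_J),
            )
            j_expected = (op.A + p.Rd) * (4 * op.cc + 8 * p.GammaStar) / (op.cc - p.GammaStar)
            assert j_from_fluorescence(r.phi_PSII, r.PAR) == pytest.approx(
                j_expected, rel=1e-9
            )


class TestGmVariableJ:
    def test_hand_example_passes_qc(self):
        est = gm_variable_j(A=20, ci=300, J=150, Rd=1, ci_star=40)
        assert est.gm == pytest.approx(0.18644, abs=1e-5)
        assert est.dCc_dA == pytest.approx(16.529, abs=1e-3)
        assert est.qc_pass and est.reason is QCReason.OK

    def test_high_sensitivity_excluded_above(self):
        est = gm_variable_j(A=20, ci=300, J=90, Rd=1, ci_star=40)
        assert est.dCc_dA == pytest.approx(1200.0, rel=1e-9)
        assert not est.qc_pass and est.reason is QCReason.ABOVE_50

    def test_low_sensitivity_excluded_below(self):
        est = gm_variable_j(A=5, ci=300, J=200, Rd=1, ci_star=40)
        assert est.dCc_dA == pytest.approx(3.099, abs=1e-3)
        assert not est.qc_pass and est.reason is QCReason.BELOW_10

    def test_window_bounds_are_strict(self):
        # solve J such that dCc/dA hits the bounds exactly, then perturb
        for target, ok in [(10.0, False), (50.0, False), (10.5, True), (49.5, True)]:
            j = _j_for_sensitivity(target, A=20.0, Rd=1.0, ci_star=40.0)
            est = gm_variable_j(A=20.0, ci=500.0, J=j, Rd=1.0, ci_star=40.0)
            assert est.dCc_dA == pytest.approx(target, rel=1e-9)
            assert est.qc_pass is ok

    def test_singular_denominator_flagged_not_raised(self):
        est = gm_variable_j(A=20, ci=300, J=84.0, Rd=1, ci_star=40)
        assert est.reason is QCReason.SINGULAR
        assert not est.qc_pass and math.isnan(est.gm)

    def test_nonpositive_gm_flagged(self):
        # cc above ci makes the drawdown negative -> negative gm
        est = gm_variable_j(A=20, ci=100, J=150, Rd=1, ci_star=40)
        assert est.gm < 0
        assert not est.qc_pass and est.reason is QCReason.NONPOSITIVE_GM

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            gm_variable_j(math.nan, 300, 150, 1, 40)

    def test_recovers_gm_for_rubp_limited_records(self):
        grid = syn.generate_variable_j_records(
            np.linspace(0.05, 0.5, 10), np.linspace(400, 1200, 5)
        )
        for row in grid.itertuples():
            est = gm_variable_j(row.A, row.ci, row.J, row.Rd, row.GammaStar)
            assert est.gm == pytest.approx(row.gm_true, rel=1e-6)

    def test_consistent_with_rubp_branch_at_returned_cc(self):
        grid = syn.generate_variable_j_records([0.2], [600.0])
        row = grid.iloc[0]
        est = gm_variable_j(row.A, row.ci, row.J, row.Rd, row.GammaStar)
        aj = row.J * (est.cc - row.GammaStar) / (4 * est.cc + 8 * row.GammaStar)
        assert aj - row.Rd == pytest.approx(row.A, rel=1e-6)
        assert cc_from_gm(row.ci, row.A, est.gm) == pytest.approx(est.cc, rel=1e-9)


class TestCcFromGm:
    def test_zero_assimilation_no_drawdown(self):
        assert cc_from_gm(315.0, 0.0, 0.2) == 315.0

    def test_consistent_with_steady_state_example(self):
        assert cc_from_gm(326.2, 13.84, 0.20) == pytest.approx(257.0, abs=0.1)

    def test_infinite_gm_limit(self):
        assert cc_from_gm(300.0, 15.0, 1e12) == pytest.approx(300.0, abs=1e-9)

    def test_nonpositive_gm_rejected(self):
        with pytest.raises(ValueError):
            cc_from_gm(300.0, 15.0, 0.0)


class TestBatchFilter:
    def _table(self):
        return pd.DataFrame({
            "A": [20.0, 20.0, 5.0, 20.0],
            "ci": [300.0, 300.0, 300.0, 300.0],
            "J": [150.0, 90.0, 200.0, 84.0],
        })

    def test_filter_is_order_independent_and_idempotent(self):
        df = self._table()
        out1 = estimate_gm_batch(df, ci_star=40, Rd=1, j_column="J")
        shuffled = df.sample(frac=1, random_state=7)
        out2 = estimate_gm_batch(shuffled, ci_star=40, Rd=1, j_column="J")
        merged = out2.sort_index()
        assert list(merged["reason"]) == list(out1["reason"])
        again = estimate_gm_batch(out1, ci_star=40, Rd=1, j_column="J")
        assert list(again["qc_pass"]) == list(out1["qc_pass"])

    def test_rows_retained_with_reasons(self):
        out = estimate_gm_batch(self._table(), ci_star=40, Rd=1, j_column="J")
        assert len(out) == 4
        assert list(out["reason"]) == ["ok", "above_50", "below_10", "singular"]

    def test_fluorescence_route_used_when_no_j_column(self):
        df = pd.DataFrame({"A": [20.0], "ci": [300.0],
                           "phi_PSII": [150.0 / (0.42 * 1000.0)], "PAR": [1000.0]})
        out = estimate_gm_batch(df, ci_star=40, Rd=1)
        assert out["gm"].iloc[0] == pytest.approx(0.18644, abs=1e-5)


def _j_for_sensitivity(s: float, A: float, Rd: float, ci_star: float) -> float:
    """Invert dCc/dA = 12 ci* J/(J-4(A+Rd))^2 for the root with J > 4(A+Rd)."""
    q = 4.0 * (A + Rd)
    # s J^2 - (2 s q + 12 ci*) J + s q^2 = 0
    b = 2.0 * s * q + 12.0 * ci_star
    disc = b * b - 4.0 * s * s * q * q
    return (b + math.sqrt(disc)) / (2.0 * s)
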