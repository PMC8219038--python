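"""Light-response, A–cc and decay fits: recovery, invariances, edge cases."""

import numpy as np
import pytest

from leafgas import synthetic as syn
from leafgas.fitting import (
    ACiModel,
    DecayModel,
    LightResponseModel,
    nrh_net_assimilation,
)


NRH_TRUTH = (0.05, 15.0, 0.7, 1.0)  # phi, asat, theta, rd


class TestLightResponse:
    def test_forward_model_hand_value(self):
        assert nrh_net_assimilation(1000.0, 0.05, 15.0, 0.7, 1.0) == pytest.approx(
            12.5017, abs=1e-4
        )

    def test_noise_free_round_trip(self, noise_free_truth):
        curve = syn.generate_light_curve(noise_free_truth, nrh_truth=NRH_TRUTH)
        fit = LightResponseModel(curve).fit()
        phi, asat, theta, rd = NRH_TRUTH
        assert fit.phi == pytest.approx(phi, rel=1e-6)
        assert fit.Asat == pytest.approx(asat, rel=1e-6)
        assert fit.theta == pytest.approx(theta, rel=1e-6)
        assert fit.Rd == pytest.approx(rd, rel=1e-6)

    def test_lcp_is_zero_crossing(self, noise_free_truth):
        curve = syn.generate_light_curve(noise_free_truth, nrh_truth=NRH_TRUTH)
        fit = LightResponseModel(curve).fit()
        assert fit.predict(fit.LCP) == pytest.approx(0.0, abs=1e-6)

    def test_zero_rd_means_zero_lcp(self, noise_free_truth):
        curve = syn.generate_light_curve(
            noise_free_truth, nrh_truth=(0.05, 15.0, 0.7, 0.0)
        )
        fit = LightResponseModel(curve).fit()
        assert fit.LCP == pytest.approx(0.0, abs=1e-6)

    def test_i75_gross_convention(self, noise_free_truth):
        curve = syn.generate_light_curve(noise_free_truth, nrh_truth=NRH_TRUTH)
        fit = LightResponseModel(curve).fit()
        gross = fit.predict(fit.I75) + fit.Rd
        assert gross == pytest.approx(0.75 * fit.Asat, abs=1e-6)

    def test_irradiance_rescaling_symmetry(self, noise_free_truth):
        curve = syn.generate_light_curve(noise_free_truth, nrh_truth=NRH_TRUTH)
        par = np.array([r.PAR for r in curve.records])
        a = np.array([r.A for r in curve.records])
        f1 = LightResponseModel(PAR=par, A=a).fit()
        f2 = LightResponseModel(PAR=2.0 * par, A=a).fit()
        assert f2.phi == pytest.approx(f1.phi / 2.0, rel=1e-6)
        assert f2.Asat == pytest.approx(f1.Asat, rel=1e-6)
        assert f2.theta == pytest.approx(f1.theta, rel=1e-4)

    def test_point_order_irrelevant(self, noise_free_truth):
        curve = syn.generate_light_curve(noise_free_truth, nrh_truth=NRH_TRUTH)
        par = np.array([r.PAR for r in curve.records])
        a = np.array([r.A for r in curve.records])
        f1 = LightResponseModel(PAR=par, A=a).fit()
        f2 = LightResponseModel(PAR=par[::-1], A=a[::-1]).fit()
        assert f2.Asat == pytest.approx(f1.Asat, rel=1e-9)

    def test_odr_mode_agrees_on_clean_data(self, noise_free_truth):
        curve = syn.generate_light_curve(noise_free_truth, nrh_truth=NRH_TRUTH)
        fit = LightResponseModel(curve).fit(method="odr")
        assert fit.Asat == pytest.approx(15.0, rel=1e-5)
        assert fit.method == "odr"

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            LightResponseModel(PAR=[0, 100, 500, 2000], A=[-1, 2, 8, 12])


class TestACiFit:
    def test_noise_free_recovery(self, noise_free_truth):
        df = syn.generate_aci_curve(noise_free_truth).to_dataframe()
        t = noise_free_truth
        fit = ACiModel(
            ci=df["ci"].to_numpy(), A=df["A"].to_numpy(), gm=t.gm_true,
            Rd=t.fvcb.Rd, GammaStar=t.fvcb.GammaStar,
        ).fit()
        assert fit.Vcmax == pytest.approx(t.fvcb.Vcmax, rel=1e-4)
        assert fit.Jmax == pytest.approx(t.fvcb.Jmax, rel=1e-4)
        assert fit.vcmax_identified and fit.jmax_identified

    def test_fitted_model_reproduces_data(self, noise_free_truth):
        df = syn.generate_aci_curve(noise_free_truth).to_dataframe()
        t = noise_free_truth
        model = ACiModel(
            ci=df["ci"].to_numpy(), A=df["A"].to_numpy(), gm=t.gm_true,
            Rd=t.fvcb.Rd, GammaStar=t.fvcb.GammaStar,
        )
        fit = model.fit()
        resid = model._model(fit.Vcmax, fit.Jmax) - df["A"].to_numpy()
        assert np.sum(resid**2) <= fit.ssr + 1e-9

    def test_overestimated_gm_biases_vcmax_low(self, noise_free_truth):
        df = syn.generate_aci_curve(noise_free_truth).to_dataframe()
        t = noise_free_truth
        kw = dict(ci=df["ci"].to_numpy(), A=df["A"].to_numpy(),
                  Rd=t.fvcb.Rd, GammaStar=t.fvcb.GammaStar)
        good = ACiModel(gm=t.gm_true, **kw).fit()
        bad = ACiModel(gm=2.0 * t.gm_true, **kw).fit()
        assert bad.Vcmax < good.Vcmax

    def test_infinite_gm_equals_fit_on_ci(self, noise_free_truth):
        df = syn.generate_aci_curve(noise_free_truth).to_dataframe()
        t = noise_free_truth
        kw = dict(ci=df["ci"].to_numpy(), A=df["A"].to_numpy(),
                  Rd=t.fvcb.Rd, GammaStar=t.fvcb.GammaStar)
        f_none = ACiModel(gm=None, **kw).fit()
        f_huge = ACiModel(gm=1e12, **kw).fit()
        assert f_huge.Vcmax == pytest.approx(f_none.Vcmax, rel=1e-6)
        assert f_huge.Jmax == pytest.approx(f_none.Jmax, rel=1e-6)

    def test_single_branch_reports_unidentified(self, noise_free_truth):
        df = syn.generate_aci_curve(
            noise_free_truth,
            ca_steps=(100, 150, 200, 250, 300, 350),  # all Rubisco-limited
        ).to_dataframe()
        t = noise_free_truth
        fit = ACiModel(
            ci=df["ci"].to_numpy(), A=df["A"].to_numpy(), gm=t.gm_true,
            Rd=t.fvcb.Rd, GammaStar=t.fvcb.GammaStar,
        ).fit()
        assert fit.vcmax_identified
        assert not fit.jmax_identified
        assert fit.Vcmax == pytest.approx(t.fvcb.Vcmax, rel=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ACiModel(ci=[100, 200, 300], A=[2, 6, 9], gm=0.2)


class TestDecayFit:
    def test_constructed_trace_recovered_exactly(self):
        t, F = syn.generate_decay_trace(250.0, amplitude=1.5, plateau=0.5)
        fit = DecayModel(t, F).fit()
        assert fit.k_relative == pytest.approx(250.0, rel=1e-6)
        assert fit.amplitude == pytest.approx(1.5, rel=1e-6)
        assert fit.plateau == pytest.approx(0.5, rel=1e-6)

    def test_constant_trace_flagged_no_decay(self):
        t = np.arange(0.0, 0.008, 0.000125)
        fit = DecayModel(t, np.full(t.size, 2.0)).fit()
        assert fit.no_decay
        assert fit.k_relative == 0.0
        assert fit.amplitude == pytest.approx(0.0, abs=1e-12)

    def test_rising_trace_flagged(self):
        t = np.arange(0.0, 0.008, 0.000125)
        fit = DecayModel(t, 1.0 + 10.0 * t).fit()
        assert fit.no_decay and fit.k_relative == 0.0

    def test_window_excludes_late_samples(self):
        t = np.arange(0.0, 0.02, 0.000125)
        F = 1.5 * np.exp(-250.0 * t) + 0.5
        F[t > 0.008] += 5.0  # corrupt beyond the window
        fit = DecayModel(t, F, window=0.008).fit()
        assert fit.k_relative == pytest.approx(250.0, rel=1e-6)

    def test_replicated_noisy_traces_average_close(self):
        ks = []
        for rep in range(3):
            for tech in range(6):
                t, F = syn.generate_decay_trace(
                    250.0, noise_frac=0.01, seed=100 * rep + tech
                )
                ks.append(DecayModel(t, F).fit().k_relative)
        assert np.mean(ks) == pytest.approx(250.0, rel=0.05)

    def test_nonmonotonic_time_rejected(self):
        with pytest.raises(ValueError):
            DecayModel([0.0, 0.002, 0.001, 0.003, 0.004], [3, 2, 1.5, 1.2, 1.0])
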