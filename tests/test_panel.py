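"""Synthetic strain-panel generator: phenotypes, light curves, transients,
NPQ time courses and decay histograms."""

from dataclasses import replace

import numpy as np
import pytest

import sigmaqe as sq

STRAIN_NAMES = {
    "wild-type", "x1KO", "x1KO+x2a", "x1KO+x3a", "x1KO+x4a",
    "x2KO", "x2KO+x2", "x2KO+x3",
}


def by_name(panel):
    return {s.name: s for s in panel}


class TestDefaultPanel:
    def test_strain_names(self):
        for acclim in ("LL", "HL"):
            assert {s.name for s in sq.default_panel(acclim)} == STRAIN_NAMES

    def test_ll_knockouts_lack_qe(self):
        p = by_name(sq.default_panel("LL"))
        assert p["x1KO"].qe_ymax == 0.0
        assert p["x1KO+x4a"].qe_ymax == 0.0

    def test_ll_qe_ordering(self):
        p = by_name(sq.default_panel("LL"))
        assert p["x2KO+x2"].qe_ymax > p["wild-type"].qe_ymax
        assert p["wild-type"].qe_ymax == p["x2KO"].qe_ymax
        assert p["x2KO"].qe_ymax > p["x1KO+x3a"].qe_ymax
        assert p["x1KO+x3a"].qe_ymax > p["x1KO+x2a"].qe_ymax
        assert p["x1KO+x2a"].qe_ymax > p["x1KO"].qe_ymax
        assert p["x1KO"].qe_ymax == p["x1KO+x4a"].qe_ymax

    def test_hl_all_strains_express_qe(self):
        assert min(s.qe_ymax for s in sq.default_panel("HL")) > 0

    def test_sigma_dark_range(self):
        for acclim in ("LL", "HL"):
            for s in sq.default_panel(acclim):
                assert 500.0 <= s.sigma_dark <= 550.0

    def test_unknown_acclimation(self):
        with pytest.raises(ValueError, match="acclimation"):
            sq.default_panel("ML")


class TestStrainSpec:
    def test_invariants(self):
        with pytest.raises(ValueError):
            sq.StrainSpec(name="bad", qe_ymax=1.5)
        with pytest.raises(ValueError):
            sq.StrainSpec(name="bad", qe_ymax=0.3, sigma_core=600.0)
        with pytest.raises(ValueError):
            sq.StrainSpec(name="bad", qe_ymax=0.3, fo=2.0, fm=1.0)

    def test_effective_qe_requires_diatoxanthin(self):
        s = sq.StrainSpec(name="wt", qe_ymax=0.4)
        assert s.effective_qe_ymax == 0.4
        assert replace(s, dtt_treated=True).effective_qe_ymax == 0.0
        assert replace(s, dt_capable=False).effective_qe_ymax == 0.0


class TestSimulateLightCurve:
    def test_sigma_rises_without_qe(self, protocol):
        s = sq.StrainSpec(name="x1KO", qe_ymax=0.0, kappa_conn=0.06)
        curve = sq.simulate_light_curve(s, protocol, 0.0)
        sig = [st.sigma_prime for st in curve.steps]
        assert np.all(np.diff(sig) >= 0)
        assert sig[-1] > sig[0]

    def test_sigma_saturation_limit(self):
        s = sq.StrainSpec(
            name="wt", qe_ymax=0.6, sigma_dark=525.0, sigma_core=110.0
        )
        proto = replace(sq.default_protocol(), step_irradiances=(0.0, 1e7))
        curve = sq.simulate_light_curve(s, proto, 0.0)
        assert curve.steps[-1].sigma_prime == pytest.approx(
            525.0 - (525.0 - 110.0) * 0.6, rel=1e-9
        )

    def test_seeded_determinism(self, protocol):
        s = sq.default_panel("LL")[0]
        a = sq.simulate_light_curve(s, protocol, 0.02, seed=7, replicate_index=3)
        b = sq.simulate_light_curve(s, protocol, 0.02, seed=7, replicate_index=3)
        for ra, rb in zip(a.steps, b.steps):
            assert ra == rb

    def test_replicates_differ(self, protocol):
        s = sq.default_panel("LL")[0]
        a = sq.simulate_light_curve(s, protocol, 0.02, seed=7, replicate_index=0)
        b = sq.simulate_light_curve(s, protocol, 0.02, seed=7, replicate_index=1)
        assert a.steps[1].f_prime != b.steps[1].f_prime

    def test_noise_free_fluorescence_ordering(self, protocol):
        for acclim in ("LL", "HL"):
            for s in sq.default_panel(acclim):
                curve = sq.simulate_light_curve(s, protocol, 0.0)
                for rec in curve.steps:
                    assert rec.fo_prime <= rec.f_prime <= rec.fm_prime
                    assert rec.fm_prime <= s.fm + 1e-12

    def test_sigma_y_line_when_qi_zero(self, protocol):
        # with no qI the downstream (sigma', Y(NPQ)) pairs sit exactly on
        # the generative line sigma_dark - (sigma_dark-sigma_core)*Y
        for acclim in ("LL", "HL"):
            for s in sq.default_panel(acclim):
                if s.qe_ymax == 0:
                    continue
                s = replace(s, qi_slope=0.0)
                table = sq.compute_params(
                    sq.simulate_light_curve(s, protocol, 0.0)
                )
                line = s.sigma_dark - (s.sigma_dark - s.sigma_core) * table["Y_NPQ"]
                assert (table["sigma_A2"] - line).abs().max() < 1e-9

    def test_dtt_equals_qe_null_twin(self, protocol):
        wt = by_name(sq.default_panel("LL"))["wild-type"]
        treated = replace(wt, dtt_treated=True)
        null = replace(wt, qe_ymax=0.0)
        a = sq.simulate_light_curve(treated, protocol, 0.02, seed=11)
        b = sq.simulate_light_curve(null, protocol, 0.02, seed=11)
        for ra, rb in zip(a.steps, b.steps):
            assert ra == rb

    def test_monotonicity(self, protocol):
        wt = replace(
            by_name(sq.default_panel("HL"))["wild-type"],
            kappa_conn=0.0, qi_slope=0.0,
        )
        table = sq.compute_params(sq.simulate_light_curve(wt, protocol, 0.0))
        assert np.all(np.diff(table["Y_NPQ"]) >= 0)
        assert np.all(np.diff(table["sigma_A2"]) <= 0)

    def test_sigma_1s_equals_sigma_noise_free(self, protocol):
        wt = by_name(sq.default_panel("LL"))["wild-type"]
        curve = sq.simulate_light_curve(wt, protocol, 0.0)
        for rec in curve.steps:
            assert rec.sigma_prime_1s == rec.sigma_prime


class TestSimulateTransient:
    def test_zero_noise_identity(self, paper_flash):
        sim = sq.simulate_transient(1.0, 3.0, 500.0, 0.0, paper_flash)
        model = sq.model_transient(1.0, 3.0, 500.0, 0.0, paper_flash)
        np.testing.assert_array_equal(sim.signal, model.signal)

    def test_first_sample_is_fo(self, paper_flash):
        sim = sq.simulate_transient(1.0, 3.0, 500.0, 0.0, paper_flash)
        assert sim.signal[0] == 1.0

    def test_flash_saturates(self, paper_flash):
        # closure 1 - exp(-9.06) for sigma = 500 A^2 under the 80 us flash
        sim = sq.simulate_transient(1.0, 3.0, 500.0, 0.0, paper_flash)
        assert sim.signal[-1] >= 0.9998 * 3.0


class TestNpqTimecourse:
    def test_qe_null_is_linear_and_non_relaxing(self):
        s = sq.StrainSpec(name="x1KO", qe_ymax=0.0)
        tc = sq.simulate_npq_timecourse(s, hl_duration_s=600.0)
        hl = tc[tc["time_s"] <= 600.0]
        rec = tc[tc["time_s"] > 600.0]
        # linear in t during the light phase
        slopes = np.diff(hl["NPQ"]) / np.diff(hl["time_s"])
        np.testing.assert_allclose(slopes, slopes[0], rtol=1e-9)
        # non-relaxing afterward
        np.testing.assert_allclose(rec["NPQ"], hl["NPQ"].iloc[-1], rtol=1e-9)

    def test_dtt_wild_type_matches_qe_null(self):
        wt = sq.StrainSpec(name="wt", qe_ymax=0.4)
        a = sq.simulate_npq_timecourse(replace(wt, dtt_treated=True))
        b = sq.simulate_npq_timecourse(replace(wt, qe_ymax=0.0))
        np.testing.assert_array_equal(a["NPQ"], b["NPQ"])

    def test_starts_at_zero_and_qe_relaxes(self):
        wt = sq.StrainSpec(name="wt", qe_ymax=0.4)
        tc = sq.simulate_npq_timecourse(wt)
        assert tc["NPQ"].iloc[0] == 0.0
        hl_end = tc[tc["time_s"] <= 600.0]["NPQ"].iloc[-1]
        assert tc["NPQ"].iloc[-1] < hl_end


class TestSimulateDecay:
    def grid(self):
        return np.arange(0.0, 16.0, 0.01)

    def test_delta_irf_identity(self):
        irf = sq.IRF.delta(self.grid())
        decay = sq.simulate_decay([1.0, 0.0, 0.0], [1.0, 0.5, 2.0], irf)
        np.testing.assert_allclose(
            decay.counts, np.exp(-self.grid() / 1.0), rtol=1e-12
        )

    def test_zero_amplitudes_flat_baseline(self):
        irf = sq.IRF.gaussian(self.grid(), 0.5, 0.1)
        decay = sq.simulate_decay([0.0, 0.0, 0.0], [0.2, 0.8, 2.0], irf,
                                  baseline=3.0)
        np.testing.assert_allclose(decay.counts, 3.0, rtol=1e-12)

    def test_convolution_preserves_area(self):
        t = self.grid()
        a, tau = [0.5, 0.3, 0.2], [0.2, 0.8, 1.5]
        delta = sq.simulate_decay(a, tau, sq.IRF.delta(t))
        gauss = sq.simulate_decay(a, tau, sq.IRF.gaussian(t, 1.0, 0.1))
        assert gauss.counts.sum() == pytest.approx(
            delta.counts.sum(), rel=1e-3
        )

    def test_poisson_noise_seeded(self):
        irf = sq.IRF.delta(self.grid())
        a = sq.simulate_decay([1e4], [1.5], irf, noise_model="poisson", seed=3)
        b = sq.simulate_decay([1e4], [1.5], irf, noise_model="poisson", seed=3)
        np.testing.assert_array_equal(a.counts, b.counts)
        assert not np.array_equal(
            a.counts,
            sq.simulate_decay([1e4], [1.5], irf, noise_model="poisson",
                              seed=4).counts,
        )

    def test_unknown_noise_model(self):
        with pytest.raises(ValueError):
            sq.simulate_decay([1.0], [1.0], sq.IRF.delta(self.grid()),
                              noise_model="gamma")


class TestPanelConfig:
    def test_validation(self, protocol):
        strains = sq.default_panel("LL")
        with pytest.raises(ValueError):
            sq.PanelConfig(strains=strains, protocol=protocol, n_replicates=0)
        with pytest.raises(ValueError):
            sq.PanelConfig(strains=strains, protocol=protocol,
                           noise_rel_sd=0.6)
        with pytest.raises(ValueError):
            sq.PanelConfig(strains=[], protocol=protocol)

    def test_simulate_panel_shape(self, protocol):
        cfg = sq.PanelConfig(
            strains=sq.default_panel("LL"), protocol=protocol,
            n_replicates=2, noise_rel_sd=0.01, seed=5,
        )
        curves = sq.simulate_panel(cfg)
        assert len(curves) == 16
        assert all(len(c.steps) == 15 for c in curves)


class TestProtocolSpec:
    def test_default_is_15_steps_to_800(self, protocol):
        e = protocol.step_irradiances
        assert len(e) == 15
        assert e[0] == 0.0 and e[-1] == 800.0

    def test_invalid_irradiances(self):
        with pytest.raises(ValueError):
            sq.ProtocolSpec(step_irradiances=(100.0, 50.0))
        with pytest.raises(ValueError):
            sq.ProtocolSpec(step_irradiances=())
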