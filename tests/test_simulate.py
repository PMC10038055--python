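import numpy as np
import pytest

from vclamp.preprocess import measure_peaks
from vclamp.simulate import (
    ChannelEnsembleModel,
    E0_PC,
    StabilityError,
    iv_protocol,
    nsfa_protocol,
    simulate,
    simulate_iv_family,
    simulate_nsfa_tails,
    simulate_ssi_family,
)
from vclamp.sweeps import segment
from vclamp.inactivation import ssi_availability

from conftest import WT_CA_ACT


class TestModelInvariants:
    def test_p_inf_bounded_by_p_open_max(self):
        m = ChannelEnsembleModel(p_open_max=0.7)
        v = np.linspace(-120, 120, 200)
        p = m.p_inf(v)
        assert np.all(p >= 0) and np.all(p <= 0.7 + 1e-12)

    def test_single_channel_current_zero_at_reversal(self):
        m = ChannelEnsembleModel(gamma_ps=4.0, v_rev_mv=60.25)
        assert m.i_single_pa(60.25) == 0.0
        assert m.i_single_pa(-39.75) == pytest.approx(-0.4)

    def test_full_range_gating_charge(self):
        m = ChannelEnsembleModel(n_channels=500, q_gating_e0=12.0)
        assert m.q_inf_pc(1e6) == pytest.approx(500 * 12.0 * E0_PC, rel=1e-12)

    @pytest.mark.parametrize(
        "kw",
        [
            dict(n_channels=0),
            dict(p_open_max=1.5),
            dict(i_ss=-0.1),
            dict(inact_k_mv=6.73),
            dict(act_k_mv=-8.0),
            dict(tau_act_ms=0.0),
            dict(charge_carrier="Na"),
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            ChannelEnsembleModel(**kw)


class TestDeterministicMode:
    def test_zero_driving_force_gives_zero_ionic_current(self):
        m = ChannelEnsembleModel(q_gating_e0=0.0, noise_sd_pa=0.0, i_ss=1.0)
        proto = iv_protocol(v_from=m.v_rev_mv, v_to=m.v_rev_mv, dv=1.0)
        s, _ = simulate(m, proto, mode="deterministic")
        b0, b1 = proto.epoch_bounds()[1]
        assert np.all(s.sweeps[0, b0:b1] == 0.0)

    def test_p_open_max_zero_gives_all_zero(self):
        m = ChannelEnsembleModel(p_open_max=0.0, q_gating_e0=0.0)
        s, _ = simulate_iv_family(m, -60, 40, 10)
        assert np.all(s.sweeps == 0.0)

    def test_peak_matches_boltzmann_scaled_ohmic(self, wt_ca_iv_model):
        m = wt_ca_iv_model
        s, _ = simulate_iv_family(m, -80, 70, 5, 50, mode="deterministic")
        peaks = measure_peaks(s, 1)
        for p in peaks:
            v = p.step_level
            expect = (
                m.g_max_ns
                * (v - m.v_rev_mv)
                / (1.0 + np.exp((m.act_v05_mv - v) / m.act_k_mv))
            )
            assert p.peak == pytest.approx(expect, rel=1e-9, abs=1e-9)

    def test_dt_halving_changes_peaks_below_half_percent(self, wt_ca_iv_model):
        peaks = {}
        for rate in (25.0, 50.0):
            s, _ = simulate_iv_family(
                wt_ca_iv_model, -40, 40, 10, 50, sample_rate_khz=rate
            )
            peaks[rate] = np.array([p.peak for p in measure_peaks(s, 1)])
        rel = np.abs(peaks[50.0] - peaks[25.0]) / (np.abs(peaks[50.0]) + 1e-12)
        assert rel.max() < 0.005

    def test_range_error(self, wt_ca_iv_model):
        with pytest.raises(ValueError):
            simulate_iv_family(wt_ca_iv_model, 40, -40, 10)


class TestStochasticMode:
    def test_seed_determinism(self, nsfa_model):
        s1, _ = simulate_nsfa_tails(nsfa_model, n_sweeps=20, seed=7)
        s2, _ = simulate_nsfa_tails(nsfa_model, n_sweeps=20, seed=7)
        np.testing.assert_array_equal(s1.sweeps, s2.sweeps)
        s3, _ = simulate_nsfa_tails(nsfa_model, n_sweeps=20, seed=8)
        assert not np.array_equal(s1.sweeps, s3.sweeps)

    def test_stability_guard(self):
        m = ChannelEnsembleModel(tau_act_ms=0.05)
        proto = iv_protocol(v_from=0, v_to=0, dv=1, sample_rate_khz=50.0)
        with pytest.raises(StabilityError, match="finer"):
            simulate(m, proto, mode="stochastic")

    def test_saturated_gate_variance_is_background_only(self):
        # p_open_max=1 and V >> act_v05 everywhere: open count pinned at N
        m = ChannelEnsembleModel(
            tau_act_ms=2.0, p_open_max=1.0, i_ss=1.0, noise_sd_pa=1.5,
            q_gating_e0=0.0, act_v05_mv=-80.0, act_k_mv=5.0, seed=3,
        )
        proto = iv_protocol(v_from=20, v_to=20, dv=1, pulse_ms=20,
                            holding_mv=20.0, sample_rate_khz=10.0)
        s, truth = simulate(m, proto, mode="stochastic", n_repeats=300)
        b0, b1 = proto.epoch_bounds()[1]
        late = s.sweeps[:, b1 - 50 : b1]
        assert np.all(truth.open_fraction[:, b1 - 50 : b1] == 1.0)
        var = late.var(ddof=1)
        assert var == pytest.approx(1.5**2, rel=0.15)

    def test_binomial_variance_identity(self, nsfa_model):
        """Across-repeat variance equals i^2 * N * p(1-p) at every sample."""
        from dataclasses import replace

        m = replace(nsfa_model, noise_sd_pa=0.0)
        s, truth = simulate_nsfa_tails(m, n_sweeps=400, seed=11)
        proto = s.protocol
        b0, b1 = proto.epoch_bounds()[2]
        i_tail = m.i_single_pa(-49.0)
        var = s.sweeps[:, b0:b1].var(axis=0, ddof=1)
        p = truth.open_fraction[:, b0:b1].mean(axis=0)
        oracle = i_tail**2 * m.n_channels * p * (1.0 - p)
        se = oracle * np.sqrt(2.0 / (400 - 1)) + 1e-9
        within = np.abs(var - oracle) <= 3.0 * se
        assert within.mean() > 0.95
        assert np.all(np.abs(var - oracle) <= 8.0 * se)

    def test_deterministic_equals_stochastic_mean(self):
        m = ChannelEnsembleModel(
            n_channels=400, gamma_ps=5.0, tau_act_ms=1.0, i_ss=1.0,
            noise_sd_pa=0.0, q_gating_e0=0.0, seed=5, **WT_CA_ACT,
        )
        # fine dt: the fixed-step transition sampling carries O((dt/tau)^2)
        # bias, which must stay below the Monte-Carlo SE of 2000 repeats
        proto = nsfa_protocol(sample_rate_khz=50.0)
        det, _ = simulate(m, proto, mode="deterministic")
        sto, _ = simulate(m, proto, mode="stochastic", n_repeats=2000)
        mean = sto.sweeps.mean(axis=0)
        se = sto.sweeps.std(axis=0, ddof=1) / np.sqrt(2000) + 1e-9
        z = (mean - det.sweeps[0]) / se
        # neighbouring samples are correlated over ~tau_act; judge the 3-SE
        # tolerance on decorrelated samples (every 2*tau_act)
        step = int(2.0 * m.tau_act_ms * proto.sample_rate_khz)
        zi = z[::step]
        assert np.mean(np.abs(zi)) < 1.5  # ~0.8 expected for pure MC noise
        assert np.max(np.abs(zi)) < 4.5
        assert (np.abs(z) <= 3.0).mean() > 0.9


class TestGatingCurrent:
    def test_charge_conservation_over_big_step(self):
        m = ChannelEnsembleModel(
            p_open_max=0.0, q_gating_e0=10.0, tau_gating_ms=0.3,
            gating_v05_mv=-20.0, gating_k_mv=8.0,
        )
        proto = iv_protocol(v_from=100.0, v_to=100.0, dv=1.0, pulse_ms=20.0,
                            holding_mv=-150.0)
        s, truth = simulate(m, proto)
        b0, b1 = proto.epoch_bounds()[1]
        q = np.trapezoid(s.sweeps[0, b0:b1], dx=s.dt_ms)
        assert q == pytest.approx(truth.expected_q_on_pa_ms, rel=0.01)


class TestSSIFamily:
    def test_asymptotes(self):
        m = ChannelEnsembleModel(
            **WT_CA_ACT, inact_v05_mv=-16.0, inact_k_mv=-6.73, i_ss=0.2,
            tau_act_ms=0.02, tau_inact_ms=300.0, q_gating_e0=0.0,
        )
        s, _ = simulate_ssi_family(
            m, cond_levels=(-120.0, 60.0), test_level=41.0, sample_rate_khz=25.0
        )
        pts = dict(ssi_availability(s))
        assert pts[-120.0] == pytest.approx(1.0, abs=1e-3)
        assert pts[60.0] == pytest.approx(0.2, abs=2e-3)

    def test_availability_reproduces_boltzmann(self, wt_ca_ssi_model):
        m = wt_ca_ssi_model
        s, _ = simulate_ssi_family(
            m, cond_levels=tuple(range(-100, 41, 20)), test_level=41.0,
            sample_rate_khz=25.0,
        )
        h0 = m.h_inf(-89.0)
        for v, a in ssi_availability(s):
            assert a == pytest.approx(m.h_inf(v) / h0, abs=5e-4)


class TestCDI:
    def test_cdi_speeds_inactivation_for_ca_only(self):
        base = dict(
            n_channels=200, gamma_ps=20.0, tau_act_ms=0.2, tau_inact_ms=200.0,
            i_ss=0.0, q_gating_e0=0.0, cdi_rate=5e-5, **WT_CA_ACT,
        )
        proto = iv_protocol(v_from=10, v_to=10, dv=1, pulse_ms=100.0,
                            sample_rate_khz=10.0)
        ca, _ = simulate(ChannelEnsembleModel(charge_carrier="Ca", **base), proto)
        ba, _ = simulate(ChannelEnsembleModel(charge_carrier="Ba", **base), proto)
        b0, b1 = proto.epoch_bounds()[1]
        # same peak, but Ca decays further by pulse end
        assert abs(ca.sweeps[0, b1 - 1]) < abs(ba.sweeps[0, b1 - 1])
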