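import numpy as np
import pytest

from vclamp.nsfa import (
    NSFAError,
    fit_variance_mean,
    nsfa,
    nsfa_derivative_check,
    q_imax_slope,
    q_on,
    select_qon_sweep,
)
from vclamp.simulate import (
    ChannelEnsembleModel,
    iv_protocol,
    simulate,
    simulate_nsfa_tails,
)
from vclamp.sweeps import SweepSegment, segment


def expectation_fixture(i=-0.5, n=1000, b=0.0, n_pts=200):
    """Analytic binomial variance curve: I = N*p*i, var = N*p*(1-p)*i^2 + b."""
    p = np.linspace(0.02, 0.9, n_pts)
    mean = n * p * i
    var = n * p * (1 - p) * i**2 + b
    return mean, var


class TestFitVarianceMean:
    def test_exact_binomial_identity(self):
        mean, var = expectation_fixture()
        i, n, b, _, _ = fit_variance_mean(mean, var)
        assert i == pytest.approx(-0.5, rel=1e-9)
        assert n == pytest.approx(1000.0, rel=1e-9)
        assert b == pytest.approx(0.0, abs=1e-9)

    def test_offset_recovered(self):
        mean, var = expectation_fixture(b=4.0)
        *_, coeffs, _ = fit_variance_mean(mean, var)
        assert coeffs[2] == pytest.approx(4.0, rel=1e-9)

    def test_zero_variance_rejected(self):
        mean, _ = expectation_fixture()
        with pytest.raises(NSFAError, match="zero"):
            fit_variance_mean(mean, np.zeros_like(mean))

    def test_upward_parabola_rejected(self):
        mean = np.linspace(-100, -1, 50)
        var = 0.01 * mean**2 + 5.0
        with pytest.raises(NSFAError, match="saturating"):
            fit_variance_mean(mean, var)


class TestNSFA:
    def test_stochastic_recovery(self, nsfa_model):
        s, truth = simulate_nsfa_tails(nsfa_model, n_sweeps=400)
        s.capacitance_pf = 10.0
        res = nsfa(s)
        i_true = truth.i_at(-49.0)
        assert res.i == pytest.approx(i_true, rel=0.10)
        assert res.n_channels == pytest.approx(1000, rel=0.15)
        assert res.p_open == pytest.approx(0.8, rel=0.10)
        assert res.n_sweeps_used == 400

    def test_deterministic_input_raises(self, nsfa_model):
        s, _ = simulate_nsfa_tails(nsfa_model, n_sweeps=60, mode="deterministic")
        from dataclasses import replace
        with pytest.warns(UserWarning):
            with pytest.raises(NSFAError):
                nsfa(s)

    def test_sweep_floor_enforced(self, nsfa_model):
        s, _ = simulate_nsfa_tails(nsfa_model, n_sweeps=30)
        with pytest.raises(NSFAError, match="floor"):
            nsfa(s)

    def test_policy_range_warning(self, nsfa_model):
        s, _ = simulate_nsfa_tails(nsfa_model, n_sweeps=80)
        with pytest.warns(UserWarning, match="policy"):
            nsfa(s)

    def test_density_convention_10pf_1000_channels(self, nsfa_model):
        s, _ = simulate_nsfa_tails(nsfa_model, n_sweeps=400)
        s.capacitance_pf = 10.0
        res = nsfa(s)
        # 10 pF == 1000 um^2 under 1 uF/cm^2, so density = N/1000 exactly
        assert res.channel_density_per_um2 == pytest.approx(
            res.n_channels / 1000.0, rel=1e-12
        )

    def test_estimator_consistency_error_shrinks_with_sweeps(self, nsfa_model):
        from dataclasses import replace

        errors = []
        for count in (100, 200, 400, 800):
            errs = []
            for seed in (1, 2, 3, 4, 5):
                m = replace(nsfa_model, seed=seed)
                s, truth = simulate_nsfa_tails(m, n_sweeps=count, seed=seed)
                with pytest.warns(UserWarning) if count < 250 or count > 500 \
                        else np.errstate():
                    res = nsfa(s)
                errs.append(abs(res.i - truth.i_at(-49.0)))
            errors.append(np.mean(errs))
        # mean error over the seed family decreases as sweeps double
        assert errors[0] > errors[-1]
        for a, b in zip(errors, errors[1:]):
            assert b <= a * 1.15  # monotone within a small slack


class TestDerivativeCheck:
    def test_derivative_at_zero_equals_i(self):
        mean, var = expectation_fixture(b=2.0)
        i, n, b, coeffs, ssr = fit_variance_mean(mean, var)
        from vclamp.nsfa import NSFAResult

        res = NSFAResult(
            i=i, i_magnitude=abs(i), n_channels=n, b=b, p_open=0.8,
            channel_density_per_um2=None,
            mean_curve=np.column_stack([mean, var]), coefficients=coeffs,
        )
        chk = nsfa_derivative_check(res)
        assert chk.i_from_derivative == pytest.approx(i, rel=1e-12)
        assert chk.apex_current == pytest.approx(i * n / 2.0, rel=1e-9)
        assert chk.consistent

    def test_heteroscedastic_noise_flagged(self):
        rng = np.random.default_rng(0)
        mean, var = expectation_fixture()
        i, n, b, coeffs, ssr = fit_variance_mean(mean, var)
        from vclamp.nsfa import NSFAResult

        noisy = var + rng.exponential(40.0, size=var.size) * np.sign(
            np.sin(np.arange(var.size))
        )
        res = NSFAResult(
            i=i, i_magnitude=abs(i), n_channels=n, b=b, p_open=0.8,
            channel_density_per_um2=None,
            mean_curve=np.column_stack([mean, noisy]), coefficients=coeffs,
        )
        chk = nsfa_derivative_check(res)
        assert not chk.consistent


def gating_model(**kw):
    base = dict(
        p_open_max=0.0, q_gating_e0=12.0, tau_gating_ms=0.3,
        gating_v05_mv=-20.0, gating_k_mv=8.0,
    )
    base.update(kw)
    return ChannelEnsembleModel(**base)


def gating_segment(rate=50.0, v_step=60.25, window_total=50.0):
    m = gating_model()
    proto = iv_protocol(v_from=v_step, v_to=v_step, dv=5.0,
                        pulse_ms=window_total, sample_rate_khz=rate)
    s, truth = simulate(m, proto)
    return segment(s, 1)[0], m, truth


class TestQOn:
    def test_exponential_integral_within_one_percent(self):
        seg, m, truth = gating_segment()
        res = q_on(seg, window_ms=2.0, capacitance_pf=10.0)
        expect = (m.q_inf_pc(60.25) - m.q_inf_pc(-89.0)) * 1000.0
        assert res.q_on_pa_ms == pytest.approx(expect, rel=0.01)
        assert res.q_on_density == pytest.approx(res.q_on_pa_ms / 10.0)

    def test_gating_free_trace_integrates_to_zero(self):
        seg, *_ = gating_segment()
        seg.values = np.zeros_like(seg.values)
        assert q_on(seg).q_on_pa_ms == 0.0

    def test_sample_rate_doubling_stable(self):
        q1 = q_on(gating_segment(rate=50.0)[0]).q_on_pa_ms
        q2 = q_on(gating_segment(rate=100.0)[0]).q_on_pa_ms
        assert abs(q2 - q1) / abs(q1) < 0.005

    def test_additive_over_subwindows(self):
        seg, *_ = gating_segment()
        full = q_on(seg, window_ms=4.0).q_on_pa_ms
        first = q_on(seg, window_ms=2.0).q_on_pa_ms
        # integral over [2, 4] via shifted segment
        k = int(round(2.0 * seg.sample_rate_khz))
        rest = SweepSegment(
            sweep_index=0, start_ms=seg.start_ms + 2.0, end_ms=seg.end_ms,
            values=seg.values[k:], step_level=seg.step_level,
            sample_rate_khz=seg.sample_rate_khz,
        )
        second = q_on(rest, window_ms=2.0).q_on_pa_ms
        assert first + second == pytest.approx(full, rel=1e-9)

    def test_window_exceeding_epoch_raises(self):
        seg, *_ = gating_segment(window_total=1.0)
        with pytest.raises(ValueError, match="window"):
            q_on(seg, window_ms=2.0)

    def test_off_reversal_warns(self):
        seg, *_ = gating_segment(v_step=50.0)
        with pytest.warns(UserWarning, match="reversal"):
            q_on(seg, v_rev_fitted=60.25)

    def test_select_closest_sweep(self):
        m = gating_model()
        proto = iv_protocol(v_from=-80, v_to=70, dv=5.0)
        s, _ = simulate(m, proto)
        seg = select_qon_sweep(s, 60.25)
        assert seg.step_level == 60.0


class TestQImaxSlope:
    def test_exact_line(self):
        pts = [(q, 46.0 * q) for q in (1.0, 2.0, 3.0, 4.0)]
        res = q_imax_slope(pts)
        assert res.slope == pytest.approx(46.0)
        assert res.slope_se == pytest.approx(0.0, abs=1e-9)
        assert res.slope_zero_intercept == pytest.approx(46.0)

    def test_synthetic_cohort_recovers_coupling(self):
        rng = np.random.default_rng(7)
        q = rng.uniform(0.5, 5.0, size=30)
        y = 46.0 * q + rng.normal(0, 5.0, size=30)
        res = q_imax_slope(list(zip(q, y)))
        assert abs(res.slope - 46.0) < 3.0 * res.slope_se + 1e-9

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="3 cells"):
            q_imax_slope([(1.0, 46.0)])
        with pytest.raises(ValueError, match="equal"):
            q_imax_slope([(2.0, 1.0), (2.0, 2.0), (2.0, 3.0)])
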