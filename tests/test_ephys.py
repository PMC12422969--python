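import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ampardyn import synthgen
from ampardyn.ephys import (
    IVPoints,
    Sweep,
    SweepSet,
    fit_decay,
    fit_recovery,
    nsfa,
    read_sweeps_csv,
    rectification_index,
    recovery_curve,
    train_ratios,
    weighted_tau,
    write_sweeps_csv,
)
from ampardyn.errors import FitError, InsufficientDataError


class TestWeightedTau:
    def test_single_component_limit(self):
        assert weighted_tau(5.0, 3.0, 50.0, 0.0) == pytest.approx(5.0)

    def test_equal_amplitudes(self):
        assert weighted_tau(5.0, 2.0, 50.0, 2.0) == pytest.approx(27.5)

    def test_printed_example(self):
        assert weighted_tau(5.0, 3.0, 50.0, 1.0) == pytest.approx(16.25)

    def test_zero_total_amplitude(self):
        with pytest.raises(ZeroDivisionError):
            weighted_tau(5.0, 1.0, 50.0, -1.0)

    @given(st.floats(0.01, 100), st.floats(-10, -0.01))
    def test_amplitude_scale_invariance(self, c_pos, c_neg):
        base = weighted_tau(3.0, 4.0, 30.0, 2.0)
        for c in (c_pos, c_neg):
            assert weighted_tau(3.0, 4.0 * c, 30.0, 2.0 * c) == pytest.approx(base)


class TestFitDecay:
    def test_single_exponential_recovered(self):
        t = np.arange(0, 40, 0.01)
        sw = Sweep(t, -30.0 * np.exp(-t / 3.4) - 1.0)
        fit = fit_decay(sw, n_components=1)
        assert fit.tau_f == pytest.approx(3.4, abs=1e-6)
        assert fit.baseline == pytest.approx(-1.0, abs=1e-6)

    def test_biexponential_recovery_and_ratio(self):
        sw = synthgen.make_decay_trace(
            tau_f=5.0, amp_f=-60.0, tau_s=50.0, amp_s=-20.0, baseline=-2.0
        )
        fit = fit_decay(sw, n_components=2)
        assert fit.tau_f == pytest.approx(5.0, rel=1e-4)
        assert fit.tau_s == pytest.approx(50.0, rel=1e-4)
        # amplitudes are referenced to the 90%-of-peak window start t0
        t0 = fit.window[0]
        expected_ratio = (-60.0 * np.exp(-t0 / 5.0)) / (-20.0 * np.exp(-t0 / 50.0))
        assert fit.amp_f / fit.amp_s == pytest.approx(expected_ratio, rel=1e-4)
        assert fit.tau_f <= fit.tau_w_des <= fit.tau_s

    def test_recovery_at_moderate_noise(self):
        # SNR 100: peak ~80 pA, noise sd 0.8 pA
        sw = synthgen.make_decay_trace(
            tau_f=5.0, amp_f=-60.0, tau_s=50.0, amp_s=-20.0, noise_sd=0.8, seed=7
        )
        fit = fit_decay(sw, n_components=2)
        assert fit.tau_f == pytest.approx(5.0, rel=0.01)
        assert fit.tau_s == pytest.approx(50.0, rel=0.01)

    def test_flat_trace_degenerate(self):
        t = np.arange(0, 10, 0.01)
        with pytest.raises(FitError):
            fit_decay(Sweep(t, np.full_like(t, -5.0)))


class TestFitRecovery:
    def test_constraints_hold(self):
        df = synthgen.make_recovery_series(y0=0.1, a1=0.6, k1=0.2, k2=0.02)
        fit = fit_recovery(df)
        assert fit.ymax == 1.0
        big = recovery_curve(1e5, fit.y0, fit.a1, fit.k1, fit.k2, fit.m1, fit.m2, fit.ymax)
        assert big == pytest.approx(1.0, abs=1e-9)
        at_zero = recovery_curve(0.0, fit.y0, fit.a1, fit.k1, fit.k2, fit.m1, fit.m2, fit.ymax)
        assert at_zero == pytest.approx(fit.y0, abs=1e-9)

    def test_noiseless_parameter_recovery(self):
        df = synthgen.make_recovery_series(y0=0.1, a1=0.6, k1=0.2, k2=0.02)
        fit = fit_recovery(df)
        assert fit.y0 == pytest.approx(0.1, abs=1e-4)
        assert fit.a1 == pytest.approx(0.6, abs=1e-4)
        assert fit.k1 == pytest.approx(0.2, abs=1e-4)
        assert fit.k2 == pytest.approx(0.02, abs=1e-4)
        # weighted tau: (tau1*a1 + tau2*(ymax-a1-y0))/(ymax-y0)
        expected = (5.0 * 0.6 + 50.0 * 0.3) / 0.9
        assert fit.tau_w_rec == pytest.approx(expected, rel=1e-4)

    def test_too_few_points(self):
        df = pd.DataFrame({"interval_ms": [1, 2, 3], "amplitude": [0.1, 0.2, 0.3]})
        with pytest.raises(InsufficientDataError):
            fit_recovery(df)


class TestNSFA:
    def test_binomial_closed_form_parabola(self):
        # N=100, i=1, p=0.5: var = i*mean - mean^2/N = 25 at mean 50
        mean, N, i = 50.0, 100.0, 1.0
        assert i * mean - mean**2 / N == pytest.approx(25.0)

    def test_recovers_unitary_current_and_count(self):
        time = np.arange(0, 40.0, 0.1)
        spec = synthgen.ChannelSimSpec(
            n_channels=100, i_unitary=-1.0,
            popen=synthgen.popen_desensitizing(time),
            n_sweeps=60, seed=12,
        )
        res = nsfa(synthgen.make_channel_sweeps(spec))
        assert res.i == pytest.approx(-1.0, rel=0.10)
        assert res.N == pytest.approx(100.0, rel=0.15)
        assert 0 < res.popen_peak <= 1.0
        # chord conductance at -60 mV for i ~ -1 pA is ~16.7 pS
        assert res.gamma_pS == pytest.approx(1000.0 * res.i / -60.0, rel=1e-9)

    def test_parabola_vertex_identity(self):
        time = np.arange(0, 40.0, 0.1)
        spec = synthgen.ChannelSimSpec(
            n_channels=80, i_unitary=-1.5,
            popen=synthgen.popen_desensitizing(time),
            n_sweeps=40, seed=4, baseline_sd=0.5,
        )
        res = nsfa(synthgen.make_channel_sweeps(spec))
        # algebraic identity of the fitted parabola
        vertex_mean = res.i * res.N / 2.0
        vertex_var = res.i**2 * res.N / 4.0 + res.background_sign * res.sigma_o2
        fitted = res.i * vertex_mean - vertex_mean**2 / res.N + res.background_sign * res.sigma_o2
        assert fitted == pytest.approx(vertex_var, rel=1e-9)

    def test_background_sign_convention(self):
        time = np.arange(0, 40.0, 0.1)
        spec = synthgen.ChannelSimSpec(
            n_channels=100, i_unitary=-1.0,
            popen=synthgen.popen_desensitizing(time),
            n_sweeps=60, seed=12, baseline_sd=1.0,
        )
        sweeps = synthgen.make_channel_sweeps(spec)
        plus = nsfa(sweeps, background_sign=+1)
        minus = nsfa(sweeps, background_sign=-1)
        assert plus.i == pytest.approx(minus.i)
        assert plus.sigma_o2 == pytest.approx(-minus.sigma_o2)

    def test_too_few_sweeps(self):
        time = np.arange(0, 10.0, 0.1)
        spec = synthgen.ChannelSimSpec(
            n_channels=10, popen=np.full(100, 0.5), n_sweeps=5, seed=0
        )
        with pytest.raises(InsufficientDataError):
            nsfa(synthgen.make_channel_sweeps(spec))

    def test_identical_sweeps_degenerate(self):
        t = np.arange(0, 10, 0.1)
        sweeps = SweepSet([Sweep(t, np.sin(t)) for _ in range(25)])
        with pytest.raises(FitError):
            nsfa(sweeps)


class TestRectificationIndex:
    def test_ohmic_closed_form(self):
        pts, _ = synthgen.make_iv_ramp(g_nS=1.0, block=None)
        assert rectification_index(pts) == pytest.approx(2.0 / 3.0, abs=1e-9)

    def test_full_block_is_zero(self):
        pts, _ = synthgen.make_iv_ramp(
            block=lambda v: (np.asarray(v) <= 0).astype(float)
        )
        assert rectification_index(pts) == pytest.approx(0.0)

    def test_intermediate_block_matches_hand_formula(self):
        pts, _ = synthgen.make_iv_ramp(
            g_nS=2.0, block=lambda v: synthgen.boltzmann_block(v, v_half=10.0, slope=15.0)
        )
        i40 = 2.0 * 40 * (1 / (1 + np.exp((40 - 10) / 15)))
        i0 = 0.0
        im60 = 2.0 * -60 * (1 / (1 + np.exp((-60 - 10) / 15)))
        assert rectification_index(pts) == pytest.approx(-(i40 - i0) / (im60 - i0), rel=1e-6)

    @given(st.floats(0.01, 100.0))
    def test_invariant_under_current_scaling(self, scale):
        pts = IVPoints(26.6, 1.0, -60.0)
        scaled = IVPoints(26.6 * scale, 1.0 * scale, -60.0 * scale)
        assert rectification_index(scaled) == pytest.approx(rectification_index(pts), rel=1e-9)

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            rectification_index(IVPoints(10.0, 5.0, 5.0))


class TestTrainRatios:
    def test_constant_train(self):
        norm, ratios = train_ratios(np.full(5, 12.0))
        np.testing.assert_allclose(norm, 1.0)
        assert ratios["P5/P1"] == pytest.approx(1.0)

    def test_printed_arithmetic(self):
        norm, ratios = train_ratios(np.array([10.0, 8, 6, 5, 4]))
        assert ratios["P5/P1"] == pytest.approx(0.4)

    def test_short_train_has_no_p5(self):
        norm, ratios = train_ratios(np.array([10.0, 8, 6]))
        assert len(norm) == 3
        assert "P5/P1" not in ratios


class TestSweepCSV:
    def test_round_trip(self, tmp_path):
        time = np.arange(0, 5.0, 0.1)
        spec = synthgen.ChannelSimSpec(
            n_channels=10, popen=np.full(len(time), 0.3), n_sweeps=3, seed=1,
            dt_ms=0.1,
        )
        sweeps = synthgen.make_channel_sweeps(spec)
        p = tmp_path / "sweeps.csv"
        write_sweeps_csv(sweeps, p)
        back = read_sweeps_csv(p)
        assert len(back) == 3
        np.testing.assert_allclose(back.currents(), sweeps.currents(), atol=1e-9)
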