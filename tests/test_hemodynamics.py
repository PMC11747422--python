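"""Derived metrics: closed forms, wave separation, recovery from truth."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from carotidwave import units
from carotidwave.hemodynamics import (QAFitError, area_from_diameter,
                                      decompose_waves, flow_waveform,
                                      pulsatility_index, pwv_qa_loop,
                                      reflection_coefficient, youngs_modulus)
from carotidwave.synthwave import HemoTruth, synthesize_waveforms


class TestClosedForms:
    def test_area_from_diameter(self):
        assert area_from_diameter(0.5) == pytest.approx(0.19635, abs=5e-6)
        assert area_from_diameter(0.0) == 0.0
        assert area_from_diameter(1.0) == pytest.approx(4 * area_from_diameter(0.5))

    def test_flow_product_and_units(self):
        # 0.2 mm² at 100 mm/s is 1.2 mL/min
        A = np.full(16, units.mm2_to_m2(0.2))
        V = np.full(16, units.mms_to_ms(100.0))
        Q, mean_q = flow_waveform(A, V)
        assert units.m3s_to_mlmin(mean_q) == pytest.approx(1.2, rel=1e-12)
        np.testing.assert_allclose(Q, mean_q)
        assert flow_waveform(A, np.zeros(16))[1] == 0.0

    def test_pulsatility_index_example(self):
        # V_ED 10, peak 60, mean 25 → PI = 2
        V = np.array([10.0, 35.0, 60.0, 35.0, 10.0, 0.0])
        V = V + (25.0 - V.mean())  # shift to mean 25 keeps peak-foot at 50
        pi = pulsatility_index(V, v_ed=V[0])
        assert pi == pytest.approx((V.max() - V[0]) / 25.0)
        assert pulsatility_index(np.full(8, 3.0)) == 0.0

    def test_pulsatility_index_half_rectified_sinusoid(self):
        # V = b + a·max(sin, 0): symbolic mean b + a/π, peak b + a, foot b
        a, b, n = 40.0, 10.0, 1 << 16
        t = np.arange(n) / n
        V = b + a * np.clip(np.sin(2 * np.pi * t), 0.0, None)
        expected = a / (b + a / np.pi)
        assert pulsatility_index(V) == pytest.approx(expected, rel=1e-3)

    def test_youngs_modulus_example_and_scaling(self):
        E = youngs_modulus(3.0, 0.5e-3, 0.05e-3, rho=1050.0)
        assert units.pa_to_kpa(E) == pytest.approx(94.5, rel=1e-12)
        assert youngs_modulus(6.0, 0.5e-3, 0.05e-3) == pytest.approx(
            4 * youngs_modulus(3.0, 0.5e-3, 0.05e-3))
        with pytest.raises(ValueError):
            youngs_modulus(3.0, -1.0, 0.05e-3)


class TestQALoop:
    def test_reflection_free_slope_exact(self):
        truth = HemoTruth(gamma_true=0.0, noise_sd=0.0, seed=1)
        wf = synthesize_waveforms(truth, n_cycles=4)
        # single raw cycle, no averaging: exact proportionality
        n = int(round(truth.period * wf.fs))
        pwv, diag = pwv_qa_loop(wf.Q[:n], wf.A[:n])
        assert pwv == pytest.approx(truth.c_true, rel=1e-12)
        assert diag["r_squared"] == pytest.approx(1.0, abs=1e-12)

    def test_scale_consistency(self):
        truth = HemoTruth(gamma_true=0.0, noise_sd=0.0, seed=2)
        wf = synthesize_waveforms(truth, n_cycles=4)
        n = int(round(truth.period * wf.fs))
        Q, A = wf.Q[:n], wf.A[:n]
        base, _ = pwv_qa_loop(Q, A)
        both, _ = pwv_qa_loop(3.0 * Q, 3.0 * A)
        q_only, _ = pwv_qa_loop(2.0 * Q, A)
        assert both == pytest.approx(base, rel=1e-9)
        assert q_only == pytest.approx(2.0 * base, rel=1e-9)

    def test_degenerate_window_raises(self):
        flat = np.ones(64)
        with pytest.raises(QAFitError):
            pwv_qa_loop(flat, flat)


class TestWaveSeparation:
    def test_conservation_exact_for_any_input(self):
        rng = np.random.default_rng(0)
        Q = rng.normal(size=256)
        Q[40] = Q.max() + 1.0  # ensure a peak
        A = rng.normal(size=256) + 10.0
        Q_f, Q_r = decompose_waves(Q, A, pwv=2.7)
        np.testing.assert_allclose(Q_f + Q_r, Q, atol=1e-12)

    def test_reflection_free_reflected_component_vanishes(self, chain_pwv):
        truth = HemoTruth(gamma_true=0.0, noise_sd=0.0, seed=3)
        pwv, sig, _ = chain_pwv(truth)
        Q_f, Q_r = decompose_waves(sig["Q"], sig["A"], pwv)
        amp = sig["Q"].max() - sig["Q"].min()
        assert np.abs(Q_r).max() < 1e-3 * amp

    def test_recovered_reflected_wave_matches_injection(self, chain_pwv):
        truth = HemoTruth(gamma_true=0.3, tau=0.02, noise_sd=0.0, seed=4)
        pwv, sig, _ = chain_pwv(truth)
        Q_f, Q_r = decompose_waves(sig["Q"], sig["A"], pwv)
        # oracle: reflected wave is −γ·p(t−τ) on the same phase grid
        ens = sig["ens"]
        wf = synthesize_waveforms(truth, n_cycles=8, fs=2000.0)
        from carotidwave.cycle_processing import detect_systole_feet, ensemble_average
        feet = detect_systole_feet(wf.t, wf.V)
        truth_ens = ensemble_average(wf.t, {"Qr": wf.Q_r}, feet)
        qr_true = truth_ens.mean_cycle["Qr"]
        fwd_amp = units.mlmin_to_m3s(truth.q_amplitude)
        rmse = np.sqrt(np.mean((Q_r - qr_true) ** 2))
        assert rmse < 0.03 * fwd_amp

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(pwv=st.floats(0.5, 10.0), seed=st.integers(0, 1000))
    def test_resummation_property(self, pwv, seed):
        rng = np.random.default_rng(seed)
        Q = np.cumsum(rng.normal(size=128))
        A = np.cumsum(rng.normal(size=128)) + 100.0
        Q_f, Q_r = decompose_waves(Q, A, pwv)
        np.testing.assert_allclose(Q_f + Q_r, Q, atol=1e-9)


class TestReflectionCoefficient:
    @pytest.mark.parametrize("phase", [0.0, 0.7, 2.5, np.pi])
    def test_analytic_sinusoid_ratio_any_phase(self, phase):
        n = 256
        t = np.arange(n) / n
        Q_f = np.sin(2 * np.pi * t)
        Q_r = 0.3 * np.sin(2 * np.pi * t + phase)
        assert reflection_coefficient(Q_f, Q_r) == pytest.approx(0.3, abs=1e-12)

    def test_zero_reflection(self):
        n = 128
        Q_f = np.sin(2 * np.pi * np.arange(n) / n)
        assert reflection_coefficient(Q_f, np.zeros(n)) == 0.0

    def test_amplitude_invariance(self):
        n = 256
        t = np.arange(n) / n
        Q_f = np.sin(2 * np.pi * t) + 0.3 * np.sin(4 * np.pi * t)
        Q_r = 0.42 * np.sin(2 * np.pi * t + 1.0)
        rc1 = reflection_coefficient(Q_f, Q_r)
        rc2 = reflection_coefficient(5.0 * Q_f, 5.0 * Q_r)
        assert rc2 == pytest.approx(rc1 / 5.0 * 5.0, rel=1e-12)
        assert reflection_coefficient(2.0 * Q_f, Q_r) == pytest.approx(
            rc1 / 2.0, rel=1e-12)

    def test_vanishing_forward_harmonic_raises(self):
        with pytest.raises(ValueError):
            reflection_coefficient(np.ones(64), np.sin(2 * np.pi * np.arange(64) / 64))


class TestEndToEndRecovery:
    @pytest.mark.parametrize("c_true", [2.0, 3.0, 4.0, 6.0])
    @pytest.mark.parametrize("gamma", [0.0, 0.15, 0.3, 0.45])
    def test_pwv_and_gamma_recovery_grid(self, c_true, gamma, chain_pwv):
        truth = HemoTruth(c_true=c_true, gamma_true=gamma, tau=0.02,
                          noise_sd=0.0, seed=10)
        pwv, sig, _ = chain_pwv(truth)
        assert abs(pwv - c_true) / c_true < 0.05
        Q_f, Q_r = decompose_waves(sig["Q"], sig["A"], pwv)
        rc = reflection_coefficient(Q_f, Q_r)
        assert abs(rc - gamma) < 0.05
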