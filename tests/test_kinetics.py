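"""FRAP normalization/fitting and ablation recoil fitting."""

import math

import numpy as np
import pytest

from omtrack.kinetics import (
    FrapTrace,
    RecoilTrace,
    fit_frap,
    fit_recoil,
    junction_intensity_fold_change,
    normalize_frap,
)
from omtrack.synthetic import generate_frap_trace, generate_recoil_trace


# ---------------------------------------------------------------------------
# FRAP normalization


def test_normalization_endpoints():
    """I = I_max gives I_N = 1; I = I_min gives I_N = 0."""
    t = np.arange(-2, 10, dtype=float) * 20.0
    intensity = np.where(t < 0, 100.0, 20.0)
    intensity[-1] = 100.0
    refs = np.full((2, t.size), 80.0)
    out = normalize_frap(FrapTrace(t, intensity, refs))
    assert out.normalized[0] == pytest.approx(0.0)
    assert out.normalized[-1] == pytest.approx(1.0)
    assert out.i_max == pytest.approx(100.0)
    assert out.i_min == pytest.approx(20.0)


def test_bleach_correction_cancels_reference_decay():
    """A 10%-per-trace acquisition decay shared with the references cancels."""
    trace = generate_frap_trace(0.8, 0.01, noise_sd=0.0, n_points=30,
                                bleach_decay_per_s=0.1 / (30 * 20.0))
    out = normalize_frap(trace)
    expected = 0.8 * (1.0 - np.exp(-0.01 * out.recovery_times()))
    assert np.allclose(out.normalized, expected, atol=1e-6)


def test_degenerate_and_invalid_traces_rejected():
    t = np.arange(-2, 8, dtype=float) * 20.0
    flat = np.full(t.size, 50.0)
    refs = np.full((1, t.size), 80.0)
    with pytest.raises(ValueError, match="degenerate"):
        normalize_frap(FrapTrace(t, flat, refs))
    with pytest.raises(ValueError, match="positive"):
        normalize_frap(FrapTrace(t, flat, np.zeros((1, t.size))))


# ---------------------------------------------------------------------------
# FRAP fitting


def test_noiseless_round_trip_recovers_parameters_to_6_decimals():
    trace = generate_frap_trace(0.8, 0.01, noise_sd=0.0, n_points=40)
    fit = fit_frap(trace)
    assert fit.mobile_fraction == pytest.approx(0.8, abs=1e-6)
    assert fit.k_per_s == pytest.approx(0.01, abs=1e-6)
    assert fit.half_time_s == pytest.approx(math.log(2) / 0.01, abs=1e-3)


def test_half_time_identity():
    """T_1/2 * k = ln 2 for any fit, to 1e-12."""
    for a, k in [(0.5, 0.003), (0.9, 0.05), (0.98, math.log(2))]:
        fit = fit_frap(generate_frap_trace(a, k, noise_sd=0.0))
        assert fit.half_time_s * fit.k_per_s == pytest.approx(math.log(2), abs=1e-12)
    # k = ln 2 per second means a half time of exactly 1 s
    fit = fit_frap(generate_frap_trace(0.7, math.log(2), noise_sd=0.0, dt_s=0.5))
    assert fit.half_time_s == pytest.approx(1.0, abs=1e-6)


def test_recovery_rate_is_initial_slope():
    """A*k equals the finite-difference slope of the fitted curve at t = 0."""
    fit = fit_frap(generate_frap_trace(0.8, 0.01, noise_sd=0.0))
    h = 1e-6
    slope = (fit.predict(np.array([h]))[0] - fit.predict(np.array([0.0]))[0]) / h
    assert fit.recovery_rate_per_s == pytest.approx(slope, abs=1e-6)


def test_noisy_replicates_recover_k_within_5_percent():
    ks = []
    for child in np.random.SeedSequence(1).spawn(10):
        trace = generate_frap_trace(0.8, 0.01, noise_sd=0.05 * 80, n_points=40,
                                    seed=child)
        ks.append(fit_frap(trace).k_per_s)
    assert np.mean(ks) == pytest.approx(0.01, rel=0.05)


def test_parameter_recovery_bias_and_rmse_over_replicates():
    """Bias of A and k < 2% and A RMSE < 8% over 50 noisy traces; the k RMSE
    floor sits near 8-9% because I_min comes from a single noisy frame (it
    anchors the whole normalized trace), so it is checked at 10%."""
    fits = []
    for child in np.random.SeedSequence(6).spawn(50):
        trace = generate_frap_trace(0.8, 0.01, noise_sd=0.05 * 80, n_points=80,
                                    seed=child)
        fit = fit_frap(trace)
        fits.append((fit.mobile_fraction, fit.k_per_s))
    a_hat = np.array([f[0] for f in fits])
    k_hat = np.array([f[1] for f in fits])
    assert abs(a_hat.mean() - 0.8) / 0.8 < 0.02
    assert abs(k_hat.mean() - 0.01) / 0.01 < 0.02
    assert np.sqrt(np.mean((a_hat - 0.8) ** 2)) / 0.8 < 0.08
    assert np.sqrt(np.mean((k_hat - 0.01) ** 2)) / 0.01 < 0.10


def test_generated_trace_limits():
    """Normalized recovery starts at 0 and tends to the mobile fraction."""
    trace = generate_frap_trace(0.65, 0.05, noise_sd=0.0, n_points=200)
    out = normalize_frap(trace)
    assert out.normalized[0] == pytest.approx(0.0, abs=1e-9)
    assert out.normalized[-1] == pytest.approx(0.65, abs=1e-3)
    with pytest.raises(ValueError):
        generate_frap_trace(0.8, 0.01, i_max=10.0, i_min=20.0)


# ---------------------------------------------------------------------------
# recoil


def test_elastic_recoil_round_trip():
    """l_f = 1 um, T = 10 s: parameters back to 6 decimals, speed 0.1 um/s."""
    trace = generate_recoil_trace(l0_um=2.0, lf_um=1.0, t_s=10.0,
                                  mode="elastic", noise_sd=0.0)
    assert trace.normalized_recoil[0] == pytest.approx(0.0, abs=1e-12)
    assert trace.normalized_recoil[-1] == pytest.approx(0.5, abs=1e-3)
    fit = fit_recoil(trace)
    assert fit.fit_ok
    assert fit.l_f_um == pytest.approx(1.0, abs=1e-6)
    assert fit.t_s == pytest.approx(10.0, abs=1e-5)
    assert fit.initial_speed_um_per_s == pytest.approx(0.1, abs=1e-6)
    assert fit.amplitude_um == pytest.approx(1.0, abs=1e-6)


def test_constant_trace_is_degenerate():
    t = np.arange(20.0) * 2.0
    fit = fit_recoil(RecoilTrace(t, np.full(20, 2.0), 2.0))
    assert not fit.fit_ok
    assert fit.amplitude_um == 0.0


def test_viscoelastic_resorption_rejects_elastic_model():
    """Rise followed by >=50% resorption (the high-fluidity regime)."""
    trace = generate_recoil_trace(l0_um=2.0, lf_um=1.0, t_s=5.0,
                                  mode="viscoelastic", noise_sd=0.0,
                                  n_points=80, resorption_tau_s=25.0)
    fit = fit_recoil(trace)
    assert not fit.fit_ok
    assert "viscoelastic" in fit.note


def test_elastic_amplitude_bounds_fitted_curve():
    trace = generate_recoil_trace(l0_um=2.0, lf_um=0.8, t_s=12.0, noise_sd=0.0)
    fit = fit_recoil(trace)
    t = np.linspace(0, 200, 100)
    curve = fit.l_f_um * (1 - np.exp(-t / fit.t_s))
    assert np.all(curve <= fit.amplitude_um + 1e-9)


def test_recoil_parameter_validation():
    with pytest.raises(ValueError):
        generate_recoil_trace(l0_um=-1.0)
    with pytest.raises(ValueError):
        generate_recoil_trace(t_s=0.0)
    with pytest.raises(ValueError):
        RecoilTrace(np.arange(3.0), np.ones(3), 0.0)


# ---------------------------------------------------------------------------
# steady-state intensity fold change


def test_fold_change_examples():
    rng = np.random.default_rng(2)
    control = rng.normal(100.0, 5.0, 300)
    same, _ = junction_intensity_fold_change(control, control)
    assert same == pytest.approx(1.0, abs=1e-12)
    up, _ = junction_intensity_fold_change(1.5 * control, control)
    assert up == pytest.approx(1.5, abs=1e-12)
    down, _ = junction_intensity_fold_change(0.75 * control, control)
    assert down == pytest.approx(0.75, abs=1e-12)
    with pytest.raises(ValueError):
        junction_intensity_fold_change([1.0, 2.0], control)
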