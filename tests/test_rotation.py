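"""Logistic fits, pulse segmentation, cross-correlation, two-sample stats."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from omtrack.presets import GOF, WILD_TYPE
from omtrack.rotation import (
    AreaSeries,
    FitError,
    RotationSeries,
    constriction_expansion_totals,
    cross_correlation,
    fit_logistic,
    ks_statistic,
    rotation_rate,
    t_test,
)
from omtrack.synthetic import generate_area_series, generate_rotation_series
from omtrack.synthetic.schedules import logistic


def brute_force_ks(a, b):
    """Independent oracle: sup |ECDF1 - ECDF2| swept over the pooled sample."""
    pooled = np.concatenate([a, b])
    d = 0.0
    for x in pooled:
        d = max(d, abs(np.mean(a <= x) - np.mean(b <= x)))
    return d


# ---------------------------------------------------------------------------
# logistic fitting


def test_noiseless_rotation_fit_recovers_parameters_and_omega():
    """R1 = 90 deg, tau = 122.7 min gives the 11 deg/h angular velocity."""
    tau = 60.0 * 90.0 / (4.0 * 11.0)
    t = np.arange(51) * 10.0
    series = RotationSeries(t, logistic(t, 90.0, 250.0, tau))
    fit = fit_logistic(series, "rotation")
    assert fit.amplitude == pytest.approx(90.0, rel=1e-4)
    assert fit.t0 == pytest.approx(250.0, rel=1e-4)
    assert fit.tau == pytest.approx(tau, rel=1e-4)
    assert fit.rate == pytest.approx(11.0, rel=1e-3)
    assert fit.rate_fixed_amplitude(90.0) == pytest.approx(11.0, rel=1e-3)


def test_noiseless_area_fit_rate_follows_maximum_slope_formula():
    """C = 60*A1/(4*tau): A1 = 12 um^2 at tau = 180 min gives 1.0 um^2/h."""
    t = np.arange(51) * 10.0
    series = AreaSeries(t, 20.0 - logistic(t, 12.0, 250.0, 180.0))
    fit = fit_logistic(series, "area")
    assert fit.amplitude == pytest.approx(12.0, rel=1e-4)
    assert fit.tau == pytest.approx(180.0, rel=1e-4)
    assert fit.rate == pytest.approx(60.0 * 12.0 / (4.0 * 180.0), rel=1e-3)
    assert fit.plateau == pytest.approx(8.0, rel=1e-3)


def test_constant_series_raises_fit_error():
    t = np.arange(20) * 10.0
    with pytest.raises(FitError):
        fit_logistic(RotationSeries(t, np.full(20, 30.0)), "rotation")


def test_noisy_parameter_recovery_mean_rates_within_5_percent():
    """Mean Omega and C over 11 noisy trajectories stay within 5% of truth."""
    children = np.random.SeedSequence(77).spawn(11)
    omegas, cs = [], []
    for child in children:
        rs, _ = generate_rotation_series(WILD_TYPE, 51, seed=child, noise_sd_deg=2.0)
        omegas.append(fit_logistic(rs, "rotation").rate)
        ars, _ = generate_area_series(WILD_TYPE, 51, seed=child, noise_sd_um2=0.5)
        cs.append(fit_logistic(ars, "area").rate)
    assert np.mean(omegas) == pytest.approx(11.0, rel=0.05)
    assert np.mean(cs) == pytest.approx(2.5, rel=0.05)


# ---------------------------------------------------------------------------
# rate and pulse segmentation


def test_strictly_increasing_series_is_one_pulse():
    t = np.arange(20) * 10.0
    _, seg = rotation_rate(RotationSeries(t, np.linspace(0, 90, 20)))
    assert seg.n_pulses == 1
    assert seg.intervals == [(0, 20, "pulse")]


def test_sawtooth_alternates_pulse_and_anti():
    t = np.arange(40) * 10.0
    saw = np.cumsum(np.tile([5.0, 5.0, -4.0, -4.0], 10))
    _, seg = rotation_rate(RotationSeries(t, saw), window=1)
    kinds = [k for *_, k in seg.intervals]
    assert all(a != b for a, b in zip(kinds, kinds[1:]))
    assert seg.n_pulses == pytest.approx(10, abs=1)


def test_pulse_count_matches_generator_period():
    series, _ = generate_rotation_series(WILD_TYPE, 51, seed=0,
                                         noise_sd_deg=0.0, pulses=True)
    _, seg = rotation_rate(series)
    duration = series.time[-1] - series.time[0]
    expected = duration / WILD_TYPE.pulse_period_min
    assert abs(seg.n_pulses - expected) <= 1


def test_rate_window_validation():
    t = np.arange(5) * 10.0
    series = RotationSeries(t, np.linspace(0, 10, 5))
    with pytest.raises(ValueError):
        rotation_rate(series, window=5)


# ---------------------------------------------------------------------------
# constriction / expansion totals


@pytest.mark.parametrize(
    "areas, expected",
    [([20.0, 8.0], (12.0, 0.0)),
     ([20.0, 18.0, 19.0, 8.0], (13.0, 1.0))],
)
def test_constriction_expansion_hand_sums(areas, expected):
    t = np.arange(len(areas)) * 10.0
    con, exp = constriction_expansion_totals(AreaSeries(t, np.array(areas)))
    assert (con, exp) == pytest.approx(expected)


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(min_value=0.5, max_value=50.0), min_size=2, max_size=30))
def test_totals_identity_balance(areas):
    """constriction_total - expansion_total = A_first - A_last, exactly."""
    t = np.arange(len(areas)) * 10.0
    series = AreaSeries(t, np.array(areas))
    con, exp = constriction_expansion_totals(series)
    assert con - exp == pytest.approx(areas[0] - areas[-1], abs=1e-9)


def test_gof_expansion_total_exceeds_wild_type():
    """Destabilized pulses in the high-fluidity preset mean more re-expansion."""
    wt, _ = generate_area_series(WILD_TYPE, 51, seed=7, noise_sd_um2=0.0, pulses=True)
    gof, _ = generate_area_series(GOF, 51, seed=7, noise_sd_um2=0.0, pulses=True)
    assert constriction_expansion_totals(gof)[1] > constriction_expansion_totals(wt)[1]


# ---------------------------------------------------------------------------
# cross-correlation


def test_autocorrelation_peaks_at_zero():
    rng = np.random.default_rng(3)
    x = rng.normal(size=60)
    lags, corr, argmax, peak = cross_correlation(x, x, 10)
    assert argmax == 0
    assert peak == pytest.approx(1.0, abs=1e-12)


def test_shifted_series_moves_peak_to_lag():
    rng = np.random.default_rng(4)
    s = rng.normal(size=80)
    x = s[10:70]
    for ell in (-5, -2, 0, 3, 5):
        y = s[10 - ell:70 - ell]
        _, _, argmax, _ = cross_correlation(x, y, 8)
        assert argmax == ell


def test_coupled_rotation_constriction_peak_at_zero_lag():
    """Rotation and constriction share the pulse clock: the rate series
    correlate maximally at zero lag (the smooth trends alone are nearly
    lag-degenerate, so the pulsatile component carries the timing)."""
    rot, _ = generate_rotation_series(WILD_TYPE, 51, seed=11,
                                      noise_sd_deg=2.0, pulses=True)
    area, _ = generate_area_series(WILD_TYPE, 51, seed=12,
                                   noise_sd_um2=0.5, pulses=True)
    constriction = 1.0 - area.area_um2 / area.area_um2[0]
    _, _, argmax, peak = cross_correlation(np.diff(rot.angle_deg),
                                           np.diff(constriction), 10)
    assert argmax == 0
    assert peak > 0.4


def test_zero_variance_is_an_error():
    with pytest.raises(ValueError):
        cross_correlation(np.ones(20), np.arange(20.0), 5)


# ---------------------------------------------------------------------------
# two-sample statistics


def test_ks_trivial_cases():
    d, _ = ks_statistic([0.0, 0.0, 0.0, 1.0], [0.0, 0.0, 0.0, 1.0])
    assert d == pytest.approx(0.0)
    d, _ = ks_statistic([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
    assert d == pytest.approx(1.0)


@settings(derandomize=True, max_examples=40)
@given(st.integers(0, 10_000))
def test_ks_matches_brute_force_sweep(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=rng.integers(2, 40))
    b = rng.normal(loc=rng.uniform(-1, 1), size=rng.integers(2, 40))
    d, _ = ks_statistic(a, b)
    assert d == pytest.approx(brute_force_ks(a, b), abs=1e-12)


def test_t_test_detects_mean_shift():
    rng = np.random.default_rng(5)
    a = rng.normal(0.0, 1.0, 50)
    b = rng.normal(2.0, 1.0, 50)
    tstat, p = t_test(a, b)
    assert p < 1e-6
    with pytest.raises(ValueError):
        t_test([1.0], [1.0, 2.0])
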