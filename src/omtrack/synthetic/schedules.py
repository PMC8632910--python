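"""Kinematic schedules: logistic rotation/constriction with pulses.

The deterministic backbone is the 3-parameter logistic,

    R*(t) = R1 / (1 + exp(-(t - t0)/tau))
    A*(t) = A0 - A1 / (1 + exp(-(t - t0)/tau_A)),

whose maximum slope amplitude/(4 tau) reproduces the headline angular
velocity and constriction rate when scaled to hours. Pulsatility is a
zero-mean rate modulation built from a rectified sinusoid of period P:

    m(t) = beta * r_peak * (|sin(pi t / P)| - 2/pi),

integrated in closed form and added to the backbone. With beta > pi/2 the
modulated rate changes sign each period, producing the alternating
pulse / anti-rotation (constriction / expansion) intervals seen in single
clusters; the modulation integrates to zero over whole periods, so the
schedule still tracks the logistic on average.
"""

from __future__ import annotations

import numpy as np

from ..presets import GenotypePreset

__all__ = ["logistic", "pulse_modulation", "rotation_schedule", "area_schedule"]


def logistic(t, amplitude: float, t0: float, tau: float):
    """amplitude / (1 + exp(-(t - t0)/tau))."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = np.asarray(t, dtype=float)
    return amplitude / (1.0 + np.exp(-(t - t0) / tau))


def _rectified_sin_integral(t: np.ndarray, period: float) -> np.ndarray:
    """Closed-form integral of |sin(pi t / P)| from 0 to t."""
    n, r = np.divmod(t, period)
    return (period / np.pi) * (2.0 * n + 1.0 - np.cos(np.pi * r / period))


def pulse_modulation(t, period: float, rate_amplitude: float) -> np.ndarray:
    """Integrated zero-mean pulsatile term added to a schedule.

    ``rate_amplitude`` is the peak of the modulating rate (units of the
    schedule per minute). Vanishes at every multiple of the period, so the
    modulation never accumulates a net offset.
    """
    if period <= 0:
        raise ValueError("pulse period must be positive")
    t = np.asarray(t, dtype=float)
    return rate_amplitude * (_rectified_sin_integral(t, period) - (2.0 / np.pi) * t)


def rotation_schedule(t_min, preset: GenotypePreset, pulses: bool = True) -> np.ndarray:
    """Ground-truth rotation angle R*(t) in degrees at times t (minutes)."""
    base = logistic(t_min, preset.rotation_amplitude_deg,
                    preset.rotation_t0_min, preset.rotation_tau_min)
    if pulses and preset.pulse_amplitude > 0:
        peak_rate = preset.rotation_amplitude_deg / (4.0 * preset.rotation_tau_min)
        base = base + pulse_modulation(
            t_min, preset.pulse_period_min, preset.pulse_amplitude * peak_rate
        )
    return base


def area_schedule(t_min, preset: GenotypePreset, pulses: bool = True) -> np.ndarray:
    """Ground-truth cluster apical area A*(t) in um^2 at times t (minutes).

    Pulses are constriction pulses: the modulation is subtracted, so the
    area shrinks fastest at pulse peaks and re-expands in between.
    """
    base = preset.area_baseline_um2 - logistic(
        t_min, preset.area_amplitude_um2, preset.area_t0_min, preset.area_tau_min
    )
    if pulses and preset.pulse_amplitude > 0:
        peak_rate = preset.area_amplitude_um2 / (4.0 * preset.area_tau_min)
        base = base - pulse_modulation(
            t_min, preset.pulse_period_min, preset.pulse_amplitude * peak_rate
        )
    return base
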