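"""Synthetic time-series generators with known ground truth.

Rotation/area series follow the preset's kinematic schedules with optional
Gaussian measurement noise; FRAP traces follow the single-exponential
recovery forward model (with an explicit acquisition-bleaching decay shared
by the ROI and the unbleached reference junctions); recoil traces follow
the elastic (or viscoelastic) post-ablation model. Every generator takes a
seed and returns the parameters it used, so downstream fits can be checked
against truth.
"""

from __future__ import annotations

import numpy as np

from ..kinetics import FrapTrace, RecoilTrace
from ..presets import GenotypePreset
from ..rotation import AreaSeries, RotationSeries
from .schedules import area_schedule, rotation_schedule

__all__ = [
    "generate_rotation_series",
    "generate_area_series",
    "generate_frap_trace",
    "generate_recoil_trace",
]


def _times(n_frames: int, interval_min: float) -> np.ndarray:
    if n_frames < 3:
        raise ValueError("need at least 3 frames")
    return np.arange(n_frames, dtype=float) * interval_min


def generate_rotation_series(
    preset: GenotypePreset,
    n_frames: int = 51,
    seed: int = 0,
    noise_sd_deg: float | None = None,
    pulses: bool = False,
) -> tuple[RotationSeries, np.ndarray]:
    """One rotation trajectory sampled at the preset's frame interval.

    Returns (series, true noiseless schedule). ``noise_sd_deg`` defaults to
    the preset's measurement noise; pass 0 for a noiseless trajectory.
    """
    t = _times(n_frames, preset.frame_interval_min)
    truth = rotation_schedule(t, preset, pulses=pulses)
    sd = preset.noise_sd_deg if noise_sd_deg is None else noise_sd_deg
    rng = np.random.default_rng(seed)
    noisy = truth + rng.normal(0.0, sd, size=t.size) if sd > 0 else truth.copy()
    return RotationSeries(t, noisy), truth


def generate_area_series(
    preset: GenotypePreset,
    n_frames: int = 51,
    seed: int = 0,
    noise_sd_um2: float | None = None,
    pulses: bool = False,
) -> tuple[AreaSeries, np.ndarray]:
    """One cluster-area trajectory; returns (series, true schedule)."""
    t = _times(n_frames, preset.frame_interval_min)
    truth = area_schedule(t, preset, pulses=pulses)
    sd = preset.noise_sd_um2 if noise_sd_um2 is None else noise_sd_um2
    rng = np.random.default_rng(seed)
    noisy = truth + rng.normal(0.0, sd, size=t.size) if sd > 0 else truth.copy()
    noisy = np.maximum(noisy, 1e-3)  # areas stay positive
    return AreaSeries(t, noisy), truth


def generate_frap_trace(
    mobile_fraction: float,
    k_per_s: float,
    i_max: float = 100.0,
    i_min: float = 20.0,
    noise_sd: float = 0.0,
    n_points: int = 30,
    dt_s: float = 20.0,
    seed: int = 0,
    n_prebleach: int = 5,
    n_references: int = 2,
    bleach_decay_per_s: float = 0.0,
) -> FrapTrace:
    """Forward-model FRAP trace: recovery plus acquisition bleaching.

    The true ROI signal is ``i_min + (i_max - i_min) * A (1 - exp(-k t))``
    for t >= 0 and ``i_max`` pre-bleach; both the ROI and the reference
    junctions are multiplied by the shared acquisition-bleaching decay
    ``exp(-bleach_decay_per_s * t_acq)`` (t_acq from the first acquired
    frame), then Gaussian noise is added. Defaults follow the study's
    20-s frame interval.
    """
    if not (0 < mobile_fraction <= 1):
        raise ValueError("mobile fraction must be in (0, 1]")
    if k_per_s <= 0 or dt_s <= 0:
        raise ValueError("k and dt must be positive")
    if i_max <= i_min:
        raise ValueError("i_max must exceed i_min")
    rng = np.random.default_rng(seed)
    t = (np.arange(n_prebleach + n_points) - n_prebleach) * dt_s
    post = t >= 0
    true = np.full(t.size, float(i_max))
    true[post] = i_min + (i_max - i_min) * mobile_fraction * (1.0 - np.exp(-k_per_s * t[post]))
    decay = np.exp(-bleach_decay_per_s * (t - t[0]))
    intensity = true * decay
    refs = np.tile(i_max * decay, (n_references, 1))
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=t.size)
        refs = refs + rng.normal(0.0, noise_sd, size=refs.shape)
    return FrapTrace(t, intensity, refs)


def generate_recoil_trace(
    l0_um: float = 2.0,
    lf_um: float = 1.0,
    t_s: float = 10.0,
    mode: str = "elastic",
    noise_sd: float = 0.0,
    n_points: int = 40,
    dt_s: float = 2.0,
    seed: int = 0,
    resorption_tau_s: float | None = None,
) -> RecoilTrace:
    """Forward-model ablation recoil trace (2-s sampling by default).

    Elastic mode: l(t) = l0 + lf (1 - exp(-t/T)). Viscoelastic mode: the
    same rise multiplied by a decaying envelope exp(-t/tau_r), returning
    the vertex distance toward its pre-cut value — the regime where the
    elastic exponential fit is rejected.
    """
    if l0_um <= 0:
        raise ValueError("l0 must be positive")
    if t_s <= 0:
        raise ValueError("recoil time constant T must be positive")
    if mode not in ("elastic", "viscoelastic"):
        raise ValueError("mode must be 'elastic' or 'viscoelastic'")
    rng = np.random.default_rng(seed)
    t = np.arange(n_points, dtype=float) * dt_s
    rise = lf_um * (1.0 - np.exp(-t / t_s))
    if mode == "viscoelastic":
        tau_r = resorption_tau_s if resorption_tau_s is not None else 5.0 * t_s
        rise = rise * np.exp(-t / tau_r)
    dist = l0_um + rise
    if noise_sd > 0:
        dist = dist + rng.normal(0.0, noise_sd, size=t.size)
    return RecoilTrace(t, dist, l0_um)
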