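"""Junction turnover and tension kinetics: FRAP and laser-ablation recoil.

FRAP traces of junctional E-cadherin are corrected for acquisition
bleaching against unbleached reference junctions, normalized as

    I_N(t) = (I(t) - I_min) / (I_max - I_min)

with I_max the pre-bleach intensity and I_min the intensity immediately
after bleaching, and fitted to the single-exponential recovery

    I_N(t) = A (1 - exp(-k t))

where A is the mobile fraction. The recovery rate is the initial slope
A*k, and the half recovery time is T_1/2 = ln 2 / k.

Ablation recoil traces l(t) (distance between the two vertices of the cut
junction) are expressed as normalized recoil (l(t) - l0)/l0 and fitted to
L = l_f (1 - exp(-t/T)); initial recoil speed is l_f/T and the recoil
amplitude is l_f. Viscoelastic traces — an initial recoil immediately
resorbed back toward the pre-cut distance — are flagged as not fittable
by the elastic model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "FrapTrace",
    "FrapFit",
    "RecoilTrace",
    "RecoilFit",
    "normalize_frap",
    "fit_frap",
    "fit_recoil",
    "junction_intensity_fold_change",
]


@dataclass
class FrapTrace:
    """A FRAP recording: ROI intensity plus unbleached reference junctions.

    ``time_s`` has t = 0 at bleach onset; pre-bleach frames carry negative
    times. ``references`` is (n_refs, n_t) and shares the time axis.
    """

    time_s: np.ndarray
    intensity: np.ndarray
    references: np.ndarray
    i_min: float | None = None
    i_max: float | None = None
    normalized: np.ndarray | None = None  # post-bleach I_N(t)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.references = np.atleast_2d(np.asarray(self.references, dtype=float))
        if self.intensity.shape != self.time_s.shape:
            raise ValueError("intensity and time must have equal length")
        if self.references.shape[1] != self.time_s.size:
            raise ValueError("reference traces must share the ROI time axis")

    @property
    def post_bleach(self) -> np.ndarray:
        return self.time_s >= 0

    def recovery_times(self) -> np.ndarray:
        return self.time_s[self.post_bleach]


@dataclass
class FrapFit:
    """Single-exponential recovery parameters."""

    mobile_fraction: float
    k_per_s: float
    rms_residual: float = 0.0
    warning: str | None = None

    @property
    def half_time_s(self) -> float:
        """T_1/2 = -ln(0.5)/k."""
        return math.log(2.0) / self.k_per_s

    @property
    def recovery_rate_per_s(self) -> float:
        """Initial slope of the fitted recovery, A * k."""
        return self.mobile_fraction * self.k_per_s

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.mobile_fraction * (1.0 - np.exp(-self.k_per_s * np.asarray(t, dtype=float)))


@dataclass
class RecoilTrace:
    """Vertex-to-vertex distance after junction ablation."""

    time_s: np.ndarray
    distance_um: np.ndarray
    l0_um: float

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.distance_um = np.asarray(self.distance_um, dtype=float)
        if self.l0_um <= 0:
            raise ValueError("pre-ablation junction length l0 must be positive")
        if self.distance_um.shape != self.time_s.shape:
            raise ValueError("distance and time must have equal length")

    @property
    def normalized_recoil(self) -> np.ndarray:
        """(l(t) - l0)/l0; exactly 0 at t = 0 by construction."""
        return (self.distance_um - self.l0_um) / self.l0_um


@dataclass
class RecoilFit:
    """Elastic recoil fit l(t) - l0 = l_f (1 - exp(-t/T))."""

    l_f_um: float
    t_s: float
    fit_ok: bool
    rms_residual: float = 0.0
    note: str | None = None

    @property
    def amplitude_um(self) -> float:
        return self.l_f_um

    @property
    def initial_speed_um_per_s(self) -> float:
        return self.l_f_um / self.t_s


# ---------------------------------------------------------------------------
# FRAP


def normalize_frap(trace: FrapTrace, copy: bool = True, smooth: bool = True) -> FrapTrace:
    """Bleach-correct and normalize a FRAP trace (fills ``normalized``).

    The ROI intensity is multiplied by the coefficient of bleach
    c(t) = ref(0) / ref(t), where ref averages all supplied unbleached
    reference junctions (correcting the shared acquisition bleaching). By
    default the coefficient is taken from a fitted exponential decay of the
    mean reference rather than the raw frame-by-frame ratio, so reference
    shot noise is not injected into the ROI trace (exact for any true
    exponential decay). I_max is the mean of the corrected pre-bleach
    frames, I_min the first corrected post-bleach frame.
    """
    if trace.references.size == 0:
        raise ValueError("at least one reference junction trace is required")
    ref = trace.references.mean(axis=0)
    if np.any(ref <= 0):
        raise ValueError("reference intensity must stay positive for bleach correction")
    if smooth and ref.size >= 3:
        t_acq = trace.time_s - trace.time_s[0]
        slope, intercept = np.polyfit(t_acq, np.log(ref), 1)
        ref = np.exp(intercept + slope * t_acq)
    corrected = trace.intensity * (ref[0] / ref)
    pre = trace.time_s < 0
    post = ~pre
    if not np.any(post):
        raise ValueError("trace has no post-bleach frames")
    i_max = float(np.mean(corrected[pre])) if np.any(pre) else float(corrected[0])
    i_min = float(corrected[post][0])
    if i_max <= i_min:
        raise ValueError("degenerate trace: I_max must exceed I_min")
    i_n = (corrected[post] - i_min) / (i_max - i_min)
    out = FrapTrace(trace.time_s.copy(), trace.intensity.copy(),
                    trace.references.copy()) if copy else trace
    out.i_min, out.i_max, out.normalized = i_min, i_max, i_n
    return out


def fit_frap(trace: FrapTrace, fit_offset: bool = True) -> FrapFit:
    """Fit I_N(t) = A(1 - exp(-kt)) to the normalized post-bleach trace.

    Normalizes first if needed. Initialization: A from the tail of the
    trace, k from a log-linear regression of (A - I_N). Because I_min is a
    single (noisy) frame, the whole normalized trace carries a small common
    offset error; by default a bounded intercept nuisance parameter absorbs
    it (it is exactly 0 on noiseless traces and is not reported as part of
    the mobile fraction). A mobile fraction slightly above 1 (up to 1.2) is
    tolerated to absorb normalization noise, with a warning recorded.
    """
    if trace.normalized is None:
        trace = normalize_frap(trace)
    t = trace.recovery_times()
    y = trace.normalized
    if t.size < 6:
        raise ValueError("need at least 6 post-bleach points")
    tail = y[-max(3, y.size // 5):]
    a0 = float(np.clip(np.mean(tail), 0.05, 1.2))
    # log-linear init for k on points clearly below the plateau
    mask = (a0 - y) > 0.05 * a0
    if mask.sum() >= 2 and np.ptp(t[mask]) > 0:
        slope = np.polyfit(t[mask], np.log(a0 - y[mask]), 1)[0]
        k0 = max(-slope, 1e-6)
    else:
        k0 = 1.0 / max(t[-1], 1.0)
    try:
        if fit_offset:
            model3 = lambda tt, a, k, c: c + a * (1.0 - np.exp(-k * tt))
            popt, _ = optimize.curve_fit(
                model3, t, y, p0=[a0, k0, 0.0],
                bounds=([0.0, 1e-9, -0.2], [1.2, np.inf, 0.2]), maxfev=20000
            )
            a, k, c = (float(v) for v in popt)
        else:
            model2 = lambda tt, a, k: a * (1.0 - np.exp(-k * tt))
            popt, _ = optimize.curve_fit(
                model2, t, y, p0=[a0, k0], bounds=([0.0, 1e-9], [1.2, np.inf]),
                maxfev=20000
            )
            a, k = float(popt[0]), float(popt[1])
            c = 0.0
    except (RuntimeError, ValueError) as exc:
        raise RuntimeError(f"FRAP fit did not converge: {exc}") from exc
    rms = float(np.sqrt(np.mean((y - (c + a * (1.0 - np.exp(-k * t)))) ** 2)))
    warning = None
    if a > 1.0:
        warning = "mobile fraction exceeds 1 (normalization noise)"
        warnings.warn(warning, stacklevel=2)
    return FrapFit(a, k, rms, warning)


# ---------------------------------------------------------------------------
# laser-ablation recoil


def fit_recoil(trace: RecoilTrace, resorption_threshold: float = 0.2) -> RecoilFit:
    """Fit the elastic recoil model to an ablation trace.

    Fits l(t) - l0 = l_f (1 - exp(-t/T)) by least squares. When the recoil
    is non-monotone beyond noise — the peak recoil is followed by a
    resorption of more than ``resorption_threshold`` of the peak, the
    viscoelastic regime — the exponential model is rejected and ``fit_ok``
    is False (parameters are still reported from the best attempt).
    """
    t = trace.time_s
    y = trace.distance_um - trace.l0_um
    if t.size < 5:
        raise ValueError("need at least 5 points to fit the recoil")
    peak_idx = int(np.argmax(y))
    peak = float(y[peak_idx])
    if peak <= 0 or np.ptp(y) < 1e-12 * max(trace.l0_um, 1.0):
        return RecoilFit(0.0, np.inf, False, note="degenerate: no recoil detected")
    tail = float(np.mean(y[-max(2, y.size // 10):]))
    resorbed = peak_idx < y.size - 1 and (peak - tail) > resorption_threshold * peak
    model = lambda tt, lf, T: lf * (1.0 - np.exp(-tt / T))
    t_scale = max(float(t[-1]), 1e-6)
    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=[peak, t_scale / 5.0],
            bounds=([0.0, 1e-9], [10.0 * peak, 100.0 * t_scale]), maxfev=20000
        )
        lf, T = float(popt[0]), float(popt[1])
        rms = float(np.sqrt(np.mean((y - model(t, lf, T)) ** 2)))
    except (RuntimeError, ValueError):
        lf, T, rms = peak, t_scale / 5.0, float("inf")
        resorbed = True
    note = "viscoelastic: recoil resorbed; exponential model rejected" if resorbed else None
    return RecoilFit(lf, T, not resorbed, rms, note)


# ---------------------------------------------------------------------------
# steady-state junction intensity


def junction_intensity_fold_change(test_intensities, control_intensities) -> tuple[float, float]:
    """Fold change of junctional intensity relative to a control group.

    Each test-junction intensity is divided by the control-group mean;
    returns (mean, SD) of those ratios. Requires at least 3 junctions per
    group and a positive control mean.
    """
    test = np.asarray(test_intensities, dtype=float)
    ctrl = np.asarray(control_intensities, dtype=float)
    if test.size < 3 or ctrl.size < 3:
        raise ValueError("need at least 3 junctions per group")
    ctrl_mean = float(ctrl.mean())
    if ctrl_mean <= 0:
        raise ValueError("control mean intensity must be positive")
    ratios = test / ctrl_mean
    return float(ratios.mean()), float(ratios.std(ddof=1))
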