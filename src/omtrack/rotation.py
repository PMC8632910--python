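"""Rotation and apical-constriction kinetics.

Quantifies ommatidial cluster rotation R(t) (the signed angle of the R2-R5
centroid line relative to the morphogenetic furrow) and cluster apical area
A(t), fits the three-parameter logistic model

    R(t) = R1 / (1 + exp(-(t - t0)/tau))
    A(t) = A0 - A1 / (1 + exp(-(t - t0)/tau))

whose maximum slope, scaled to hours, defines the angular velocity
``Omega = 60*R1/(4*tau)`` [deg/h] and the constriction rate
``C = 60*A1/(4*tau)`` [um^2/h], segments the pulsatile component of the
rate into pulse / anti-rotation (or constriction / expansion) intervals,
and provides the cross-correlation and two-sample statistics used to
compare the two processes and genotype distributions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "RotationSeries",
    "AreaSeries",
    "LogisticFit",
    "PulseSegmentation",
    "FitError",
    "AlignmentError",
    "measure_rotation",
    "measure_area",
    "align_at_r7",
    "estimate_r7_frame",
    "fit_logistic",
    "rotation_rate",
    "constriction_expansion_totals",
    "cross_correlation",
    "ks_statistic",
    "t_test",
]


class FitError(RuntimeError):
    """Model fit failed to converge or the data carry no inflection."""

    def __init__(self, message: str, residuals: np.ndarray | None = None):
        super().__init__(message)
        self.residuals = residuals


class AlignmentError(RuntimeError):
    """R7 recruitment time could not be determined."""


def _as_series_arrays(time, values):
    t = np.asarray(time, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape or t.ndim != 1:
        raise ValueError("time and values must be 1-D arrays of equal length")
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise ValueError("time must be strictly increasing")
    return t, v


@dataclass
class RotationSeries:
    """Rotation angle vs. time, in degrees and minutes.

    ``time`` is conventionally aligned so t = 0 at R7 recruitment.
    Angles are unwrapped (no +-180 deg jumps between frames) and signed so
    that rotation in the annotated chiral direction is positive.
    """

    time: np.ndarray
    angle_deg: np.ndarray
    gaps: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.time, self.angle_deg = _as_series_arrays(self.time, self.angle_deg)

    @property
    def normalized(self) -> np.ndarray:
        """R(t)/90 — fraction of the full 90-degree rotation."""
        return self.angle_deg / 90.0

    def shifted(self, dt_min: float) -> "RotationSeries":
        return RotationSeries(self.time + dt_min, self.angle_deg.copy(), list(self.gaps))


@dataclass
class AreaSeries:
    """Cluster apical surface area vs. time (um^2, minutes)."""

    time: np.ndarray
    area_um2: np.ndarray
    gaps: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.time, self.area_um2 = _as_series_arrays(self.time, self.area_um2)
        if np.any(self.area_um2 <= 0):
            raise ValueError("areas must be positive")

    @property
    def normalized_constriction(self) -> np.ndarray:
        """1 - A(t)/A0 with A0 the area at the first time point."""
        return 1.0 - self.area_um2 / self.area_um2[0]

    def shifted(self, dt_min: float) -> "AreaSeries":
        return AreaSeries(self.time + dt_min, self.area_um2.copy(), list(self.gaps))


@dataclass
class LogisticFit:
    """Fitted logistic parameters and the derived maximum-slope rate.

    ``rate = 60 * amplitude / (4 * tau)`` is Omega (deg/h) for rotation and
    C (um^2/h) for area. ``baseline`` is 0 for rotation and A0 for area;
    for area fits ``plateau = baseline - amplitude`` is the final apical
    surface area.
    """

    kind: str  # "rotation" | "area"
    amplitude: float
    baseline: float
    t0: float
    tau: float
    rms_residual: float
    tau_at_bound: bool = False

    @property
    def rate(self) -> float:
        return 60.0 * self.amplitude / (4.0 * self.tau)

    def rate_fixed_amplitude(self, amplitude: float = 90.0) -> float:
        """Rate computed with a fixed nominal amplitude (e.g. the full 90 deg)."""
        return 60.0 * amplitude / (4.0 * self.tau)

    @property
    def plateau(self) -> float:
        return self.baseline - self.amplitude if self.kind == "area" else self.baseline + self.amplitude

    @property
    def constriction_fraction(self) -> float:
        """Total fractional constriction amplitude/baseline (area fits)."""
        if self.kind != "area":
            raise ValueError("constriction fraction defined for area fits only")
        return self.amplitude / self.baseline

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        s = 1.0 / (1.0 + np.exp(-(t - self.t0) / self.tau))
        if self.kind == "area":
            return self.baseline - self.amplitude * s
        return self.baseline + self.amplitude * s


@dataclass
class PulseSegmentation:
    """Alternating pulse / anti intervals of a smoothed rate series.

    Intervals are (start_index, end_index_exclusive, klass) with klass
    ``"pulse"`` where the smoothed rate is positive and ``"anti"``
    elsewhere; they partition the rate series.
    """

    intervals: list[tuple[int, int, str]]

    @property
    def n_pulses(self) -> int:
        return sum(1 for *_, k in self.intervals if k == "pulse")


# ---------------------------------------------------------------------------
# measurement from tracked movies


def _signed_angle_to_axis(vec: np.ndarray, axis_deg: float) -> float:
    """Signed angle (deg) from the furrow axis to ``vec``, in (-180, 180]."""
    axis = np.array([math.cos(math.radians(axis_deg)), math.sin(math.radians(axis_deg))])
    ang = math.degrees(math.atan2(vec[0] * axis[1] - vec[1] * axis[0], vec @ axis))
    return -ang  # positive = counterclockwise in x-right / y-up convention


def measure_rotation(movie, annotation) -> RotationSeries:
    """Per-frame signed angle of the R2->R5 centroid line to the furrow.

    The angle is unwrapped across frames (a centroid line is a director, so
    raw angles are only defined modulo 180 deg) and signed so the annotated
    chirality is positive. Frames where R2 or R5 is missing are recorded as
    gaps and excluded — never interpolated.
    """
    from .io import build_cell_graph  # local import to avoid cycle

    r2 = annotation.cell_for_role("R2")
    r5 = annotation.cell_for_role("R5")
    sign = 1.0 if annotation.chirality == "counterclockwise" else -1.0
    times, angles, gaps = [], [], []
    prev = None
    for f in range(movie.n_frames):
        geom = build_cell_graph(movie, f)
        if r2 not in geom.cells or r5 not in geom.cells:
            gaps.append(f)
            continue
        vec = geom.cells[r5].centroid_um - geom.cells[r2].centroid_um
        raw = sign * _signed_angle_to_axis(vec, annotation.furrow_axis_deg)
        if prev is not None:
            # unwrap on the 180-degree director period
            while raw - prev > 90.0:
                raw -= 180.0
            while raw - prev < -90.0:
                raw += 180.0
        prev = raw
        times.append(f * movie.frame_interval_min)
        angles.append(raw)
    series = RotationSeries(np.array(times), np.array(angles), gaps)
    # report rotation relative to the initial (pre-cluster) orientation
    series.angle_deg = series.angle_deg - series.angle_deg[0]
    return series


def measure_area(movie, annotation) -> AreaSeries:
    """Combined apical surface area of the recruited R-cells per frame.

    Before R1/R6 and R7 recruitment the sum runs over the cells recruited
    so far (the 5-cell pre-cluster, then 7, then 8 cells).
    """
    from .io import build_cell_graph

    times, areas, gaps = [], [], []
    for f in range(movie.n_frames):
        rcells = annotation.r_cells_at_frame(f)
        geom = build_cell_graph(movie, f)
        if any(c not in geom.cells for c in rcells):
            gaps.append(f)
            continue
        times.append(f * movie.frame_interval_min)
        areas.append(sum(geom.cells[c].area_um2 for c in rcells))
    return AreaSeries(np.array(times), np.array(areas), gaps)


def estimate_r7_frame(area: AreaSeries, fraction: float = 0.85) -> int:
    """Estimate the R7-recruitment frame from the constriction curve.

    Returns the index where A(t) first falls below ``fraction`` of the mean
    of its first three points — used when recruitment happened before the
    start of acquisition or is unannotated.
    """
    a = area.area_um2
    ref = float(np.mean(a[: min(3, a.size)]))
    below = np.nonzero(a < fraction * ref)[0]
    if below.size == 0:
        raise AlignmentError(
            "area never falls below the constriction threshold; cannot estimate R7 recruitment"
        )
    return int(below[0])


def align_at_r7(series, annotation=None, *, r7_frame=None, area: AreaSeries | None = None,
                frame_interval_min: float = 10.0):
    """Shift a series' time axis so t = 0 at R7 recruitment.

    The recruitment frame comes from the annotation (or ``r7_frame``); when
    unknown it is estimated from the constriction curve via
    :func:`estimate_r7_frame`.
    """
    if r7_frame is None and annotation is not None and annotation.r7_frame != "unknown":
        r7_frame = annotation.r7_frame
    if r7_frame is None:
        src = area if area is not None else (series if isinstance(series, AreaSeries) else None)
        if src is None:
            raise AlignmentError("r7 frame unknown and no area series available for estimation")
        r7_frame = estimate_r7_frame(src)
    return series.shifted(-float(r7_frame) * frame_interval_min)


# ---------------------------------------------------------------------------
# logistic fitting


def _logistic(t, amplitude, t0, tau):
    return amplitude / (1.0 + np.exp(-(t - t0) / tau))


def fit_logistic(series, kind: str | None = None) -> LogisticFit:
    """Least-squares logistic fit of a rotation or area series.

    Initialization: amplitude from the data extremes, t0 from the
    mid-amplitude crossing, tau from a quarter of the span. Bounds: tau in
    (0, total duration], amplitude in [0, 2x data range]. A series without
    an inflection (flat data) raises :class:`FitError`.
    """
    if kind is None:
        kind = "area" if isinstance(series, AreaSeries) else "rotation"
    if kind not in ("rotation", "area"):
        raise ValueError("kind must be 'rotation' or 'area'")
    t = series.time
    y = series.area_um2 if kind == "area" else series.angle_deg
    if t.size < 8:
        raise FitError("need at least 8 time points to fit the logistic")
    span = float(t[-1] - t[0])
    rng_y = float(np.ptp(y))
    scale = max(abs(np.max(y)), abs(np.min(y)), 1.0)
    if rng_y < 1e-9 * scale:
        raise FitError("series is constant: no inflection to fit", residuals=y - np.mean(y))

    if kind == "area":
        # A(t) = a0 - a1 * sigma(t)
        a0_init = float(np.max(y))
        a1_init = rng_y
        mid = a0_init - 0.5 * a1_init
        t0_init = float(t[np.argmin(np.abs(y - mid))])
        p0 = [a0_init, a1_init, t0_init, span / 4.0]
        lo = [0.0, 0.0, t[0] - span, 1e-6]
        hi = [2.0 * float(np.max(y)), 2.0 * rng_y, t[-1] + span, span]
        model = lambda tt, a0, a1, t0, tau: a0 - _logistic(tt, a1, t0, tau)
    else:
        amp_init = float(y[-1] - y[0]) or rng_y
        mid = y[0] + 0.5 * amp_init
        t0_init = float(t[np.argmin(np.abs(y - mid))])
        p0 = [amp_init, t0_init, span / 4.0]
        lo = [0.0, t[0] - span, 1e-6]
        hi = [2.0 * rng_y + 1e-9, t[-1] + span, span]
        model = _logistic
    p0 = np.clip(p0, lo, hi)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(model, t, y, p0=p0, bounds=(lo, hi), maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"logistic fit did not converge: {exc}") from exc
    resid = y - model(t, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    if kind == "area":
        a0, a1, t0, tau = popt
        fit = LogisticFit("area", float(a1), float(a0), float(t0), float(tau), rms)
    else:
        a1, t0, tau = popt
        fit = LogisticFit("rotation", float(a1), 0.0, float(t0), float(tau), rms)
    if fit.tau >= span * (1 - 1e-9):
        fit.tau_at_bound = True
        warnings.warn("fitted tau at the duration bound; rate unreliable", stacklevel=2)
    return fit


# ---------------------------------------------------------------------------
# pulses


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; shrinks the window symmetrically at edges."""
    out = np.empty_like(x, dtype=float)
    half = window // 2
    for i in range(x.size):
        lo = max(0, i - half)
        hi = min(x.size, i + half + 1)
        out[i] = np.mean(x[lo:hi])
    return out


def _segment_sign(smoothed: np.ndarray) -> PulseSegmentation:
    pos = smoothed > 0
    intervals: list[tuple[int, int, str]] = []
    start = 0
    for i in range(1, pos.size + 1):
        if i == pos.size or pos[i] != pos[start]:
            intervals.append((start, i, "pulse" if pos[start] else "anti"))
            start = i
    return PulseSegmentation(intervals)


def rotation_rate(series: RotationSeries, window: int = 3):
    """dR/dt (deg/min) with pulse segmentation.

    Centered finite differences smoothed by a centered moving average
    (default 3 frames = 30 min). A pulse is a maximal run of positive
    smoothed rate; anti-rotation intervals are the complement.
    """
    t, r = series.time, series.angle_deg
    if t.size < 3:
        raise ValueError("need at least 3 points for a rate")
    if window >= t.size:
        raise ValueError("smoothing window must be shorter than the series")
    rate = np.gradient(r, t)
    smoothed = _moving_average(rate, window)
    return smoothed, _segment_sign(smoothed)


def constriction_expansion_totals(series: AreaSeries) -> tuple[float, float]:
    """Total area lost in constriction steps and gained in expansion steps.

    constriction_total = sum |dA| over frame-pairs with dA < 0;
    expansion_total = sum dA over frame-pairs with dA > 0. The identity
    constriction_total - expansion_total = A_first - A_last holds exactly.
    """
    if series.area_um2.size < 2:
        raise ValueError("need at least 2 points")
    da = np.diff(series.area_um2)
    constriction = float(-da[da < 0].sum())
    expansion = float(da[da > 0].sum())
    return constriction, expansion


# ---------------------------------------------------------------------------
# correlation and two-sample statistics


def cross_correlation(x, y, max_lag: int):
    """Normalized cross-correlation of two z-scored series at integer lags.

    Returns (lags, correlations, argmax_lag, peak). Positive lag means y
    trails x by that many frames. At each lag the Pearson correlation of
    the overlapping segments is computed (each segment standardized over
    the overlap, so shrinking overlaps carry no edge bias toward lag 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and equal length")
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 overlapping points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance series: correlation undefined")
    max_lag = int(max_lag)
    lags = np.arange(-max_lag, max_lag + 1)
    corr = np.empty(lags.size)
    for i, ell in enumerate(lags):
        if ell >= 0:
            a, b = x[: n - ell], y[ell:]
        else:
            a, b = x[-ell:], y[: n + ell]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            corr[i] = np.nan
            continue
        corr[i] = np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb)
    peak_idx = int(np.argmax(corr))
    return lags, corr, int(lags[peak_idx]), float(corr[peak_idx])


def ks_statistic(sample1, sample2) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic D = sup|ECDF1 - ECDF2| and
    its asymptotic two-sided p-value."""
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def t_test(sample1, sample2, welch: bool = True) -> tuple[float, float]:
    """Two-tailed Student's t test (Welch variant by default)."""
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)
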