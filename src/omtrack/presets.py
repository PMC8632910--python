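"""Genotype presets for the synthetic tissue generator.

The wild-type kinetic defaults are derived by inverting the headline rate
formulas of the live-imaging study this package quantifies:

* rotation: a 90-degree logistic with angular velocity
  ``Omega = 60 * amplitude / (4 * tau)`` [deg/h]; ``Omega = 11 deg/h``
  pins ``tau = 60 * 90 / (4 * 11) ~ 122.7 min``.
* apical area: ``A(t) = A0 - A1 / (1 + exp(-(t - t0)/tau))`` with
  constriction rate ``C = 60 * A1 / (4 * tau) = 2.5 um^2/h``, a plateau
  ``A0 - A1 ~ 8 um^2`` and a ~60% total constriction, which together give
  ``(A0, A1, tau) = (20 um^2, 12 um^2, 72 min)``.

Loss-of-function ("lof", low tissue fluidity) and gain-of-function ("gof",
high fluidity) presets are qualitative transformations of wild type: motility
and neighbor-exchange scale down/up, constriction-pulse stabilization is
altered, and the rotation endpoint under-/over-shoots. Presets are strictly
ordered lof < wild_type < gof in interommatidial motility and exchange rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "GenotypePreset",
    "WILD_TYPE",
    "LOF",
    "GOF",
    "PRESETS",
    "get_preset",
    "rate_from_logistic",
    "tau_from_rate",
]

#: headline wild-type numbers the defaults are derived from
OMEGA_WT_DEG_PER_H = 11.0
C_WT_UM2_PER_H = 2.5
ROTATION_AMPLITUDE_WT_DEG = 90.0
AREA_BASELINE_WT_UM2 = 20.0
AREA_AMPLITUDE_WT_UM2 = 12.0


def rate_from_logistic(amplitude: float, tau_min: float) -> float:
    """Maximum slope of a logistic, scaled to per-hour units.

    ``rate = 60 * amplitude / (4 * tau)`` — the angular velocity Omega when
    the amplitude is in degrees, the constriction rate C when it is in um^2.
    """
    if tau_min <= 0:
        raise ValueError("tau must be positive")
    return 60.0 * amplitude / (4.0 * tau_min)


def tau_from_rate(amplitude: float, rate_per_h: float) -> float:
    """Invert ``rate = 60 * amplitude / (4 * tau)`` for tau in minutes."""
    if rate_per_h <= 0:
        raise ValueError("rate must be positive")
    return 60.0 * amplitude / (4.0 * rate_per_h)


@dataclass(frozen=True)
class GenotypePreset:
    """All tunable parameters of one synthetic genotype.

    Rates are per the study's sampling: frames every ``frame_interval_min``
    minutes, exchange counts per ommatidium per frame-pair, division and
    delamination planted per 90-min bin per ommatidium.
    """

    name: str
    rotation_amplitude_deg: float = ROTATION_AMPLITUDE_WT_DEG
    rotation_tau_min: float = tau_from_rate(ROTATION_AMPLITUDE_WT_DEG, OMEGA_WT_DEG_PER_H)
    rotation_t0_min: float = 250.0
    area_baseline_um2: float = AREA_BASELINE_WT_UM2
    area_amplitude_um2: float = AREA_AMPLITUDE_WT_UM2
    area_tau_min: float = tau_from_rate(AREA_AMPLITUDE_WT_UM2, C_WT_UM2_PER_H)
    area_t0_min: float = 250.0
    pulse_period_min: float = 80.0
    #: rate-modulation amplitude as a multiple of the peak logistic rate;
    #: must comfortably exceed pi/2 for the 10-min-sampled, smoothed rate to
    #: alternate sign (anti-rotation / expansion intervals between pulses)
    pulse_amplitude: float = 4.0
    exchange_rate_start: float = 7.0
    exchange_rate_end: float = 4.0
    #: planted events per ommatidium per 90-min bin
    division_schedule: tuple[int, ...] = (3, 2, 1, 0, 0, 0)
    delamination_schedule: tuple[int, ...] = (0, 1, 2, 2, 1, 0)
    ic_motility_um_per_frame: float = 0.10
    noise_sd_deg: float = 2.0
    noise_sd_um2: float = 0.5
    frame_interval_min: float = 10.0
    r16_frame: int = 2
    r7_frame: int = 4

    def __post_init__(self) -> None:
        if self.rotation_tau_min <= 0 or self.area_tau_min <= 0:
            raise ValueError("time constants must be positive")
        if not (self.area_baseline_um2 > self.area_amplitude_um2 > 0):
            raise ValueError("require area_baseline > area_amplitude > 0")
        if self.frame_interval_min <= 0:
            raise ValueError("frame interval must be positive")
        for r in (
            self.exchange_rate_start,
            self.exchange_rate_end,
            self.ic_motility_um_per_frame,
            self.noise_sd_deg,
            self.noise_sd_um2,
            self.pulse_amplitude,
        ):
            if r < 0:
                raise ValueError("rates and noise levels must be non-negative")
        if any(c < 0 for c in self.division_schedule + self.delamination_schedule):
            raise ValueError("event schedules must be non-negative")

    @property
    def omega_deg_per_h(self) -> float:
        return rate_from_logistic(self.rotation_amplitude_deg, self.rotation_tau_min)

    @property
    def constriction_rate_um2_per_h(self) -> float:
        return rate_from_logistic(self.area_amplitude_um2, self.area_tau_min)

    @property
    def plateau_area_um2(self) -> float:
        return self.area_baseline_um2 - self.area_amplitude_um2


WILD_TYPE = GenotypePreset(name="wild_type")

# Low-fluidity loss of function: under-rotation, damped pulses, caged ICs,
# fewer exchanges and delaminations.
LOF = replace(
    WILD_TYPE,
    name="lof",
    rotation_amplitude_deg=50.0,
    pulse_amplitude=2.0,
    exchange_rate_start=WILD_TYPE.exchange_rate_start * 0.3,
    exchange_rate_end=WILD_TYPE.exchange_rate_end * 0.3,
    delamination_schedule=(0, 1, 1, 1, 0, 0),
    ic_motility_um_per_frame=WILD_TYPE.ic_motility_um_per_frame * 0.3,
)

# High-fluidity gain of function: variable endpoint, unstable pulses with
# long expansion periods, highly motile ICs, sustained exchange.
GOF = replace(
    WILD_TYPE,
    name="gof",
    pulse_amplitude=6.0,
    exchange_rate_start=10.0,
    exchange_rate_end=6.0,
    delamination_schedule=(1, 2, 2, 2, 1, 1),
    ic_motility_um_per_frame=WILD_TYPE.ic_motility_um_per_frame * 2.5,
    noise_sd_deg=8.0,
)

PRESETS: dict[str, GenotypePreset] = {p.name: p for p in (WILD_TYPE, LOF, GOF)}


def get_preset(name: str) -> GenotypePreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None
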