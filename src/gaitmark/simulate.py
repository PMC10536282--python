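"""Seeded simulator of land and underwater treadmill gait recordings.

The generator emulates the statistical and phase structure the analysis
assumes, for one instrumented foot:

* periodic strides at the four protocol speeds, with stride durations drawn
  from a truncated normal (stride-to-stride jitter);
* a smooth periodic sagittal-plane gyro waveform whose negative-to-positive
  zero-crossing coincides with initial contact (IC) on land but *lags* IC
  underwater (the fluid-drag timing discrepancy the transfer experiments
  probe), realized as a periodic cubic spline through fixed control points;
* a stance-shaped vertical force channel — zero in swing, a steep-shouldered
  double hump in stance — whose peak scales with (1 - support fraction) x
  bodyweight, so 30%/50% unloading halves or nearly halves the peak load;
* per-condition gyro amplitude attenuation (stronger underwater), a
  per-subject amplitude multiplier, and additive Gaussian sensor noise on
  the gyro channel.

Every recording carries the exact ground-truth event set used to build it:
IC at the first stance sample (force support onset), FO at the first swing
sample after stance. With noise and jitter disabled, a 10 N threshold
detector applied to the raw force recovers these events exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .core import (
    ConfigurationError,
    EventSet,
    GaitRecording,
    LAND_SUPPORTS,
    SPEEDS,
    SUPPORT_FRACTION,
    WATER_SUPPORTS,
)

__all__ = [
    "SimConfig",
    "TemplateParams",
    "stride_template",
    "simulate_recording",
    "simulate_cohort",
    "GYRO_CONTROL_POINTS",
]

#: (phase, value) control points of the unit-amplitude gyro template,
#: pinned so tests are stable. Phases <= 1 are fractions of the stance
#: interval, phases in (1, 2] fractions of the swing interval. The shape
#: mirrors the characteristic foot-gyro waveform: a negative-to-positive
#: zero-crossing exactly at IC (phase 0), a low positive heel-rocker bump
#: through stance, a positive-to-negative crossing just before FO falling
#: into the plantarflexion trough around FO, the dominant positive
#: dorsiflexion peak at mid-swing, and a shallow pre-IC trough closing the
#: cycle. Four sign changes per stride (two per direction).
GYRO_CONTROL_POINTS = (
    (0.00, 0.0),    # IC: neg->pos crossing
    (0.12, 0.15),
    (0.25, 0.20),   # heel-rocker bump
    (0.50, 0.10),
    (0.75, 0.05),
    (0.92, 0.0),    # pos->neg crossing just before FO
    (1.00, -0.40),  # stance/swing boundary: entering the FO trough
    (1.12, -0.45),  # plantarflexion trough
    (1.30, 0.0),    # neg->pos crossing, early swing
    (1.60, 1.0),    # dominant mid-swing dorsiflexion peak
    (1.75, 0.35),
    (1.82, 0.0),    # pos->neg crossing, late swing
    (1.90, -0.35),  # pre-IC trough
    (2.00, 0.0),    # back to the IC crossing
)

_ENVIRONMENT_OF = {s: "land" for s in LAND_SUPPORTS}
_ENVIRONMENT_OF.update({s: "water" for s in WATER_SUPPORTS})


def _default_stride_times() -> dict:
    # plausible able-bodied stride durations per belt speed (s)
    return {0.4: 1.8, 0.8: 1.4, 1.2: 1.1, 1.6: 0.95}


def _default_amp_scale() -> dict:
    # land harness support barely changes foot swing amplitude; water drag
    # attenuates it substantially
    return {"none": 1.0, "bws30": 0.95, "bws50": 0.90, "waist": 0.75, "chest": 0.65}


def _default_stance_fraction() -> dict:
    # stance occupies a larger share of the stride at slower speeds
    return {0.4: 0.66, 0.8: 0.63, 1.2: 0.60, 1.6: 0.57}


def _default_ic_lead() -> dict:
    # seconds by which IC precedes the gyro negative-to-positive crossing
    return {"land": 0.0, "water": 0.06}


@dataclass
class SimConfig:
    """Cohort simulation settings; defaults mirror the study conditions."""

    n_subjects: int = 12
    speeds: tuple = SPEEDS
    conditions: tuple = LAND_SUPPORTS
    duration: float = 180.0
    fs: float = 100.0
    stride_time: dict = field(default_factory=_default_stride_times)
    stance_fraction: float | dict = field(default_factory=_default_stance_fraction)
    ic_lead: dict = field(default_factory=_default_ic_lead)
    amp_scale: dict = field(default_factory=_default_amp_scale)
    jitter_cv: float = 0.03
    amp_jitter_cv: float = 0.05
    noise_sd: float = 5.0
    bodyweight: float = 700.0
    subject_amp_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        fractions = (
            self.stance_fraction.values()
            if isinstance(self.stance_fraction, dict)
            else (self.stance_fraction,)
        )
        if any(not 0 < u < 1 for u in fractions):
            raise ConfigurationError("stance_fraction must lie in (0, 1)")
        if self.jitter_cv < 0 or self.amp_jitter_cv < 0 or self.noise_sd < 0:
            raise ConfigurationError(
                "jitter_cv, amp_jitter_cv and noise_sd must be >= 0"
            )
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        unknown = [c for c in self.conditions if c not in SUPPORT_FRACTION]
        if unknown:
            raise ConfigurationError(f"unknown conditions: {unknown}")
        unknown_speeds = [
            s for s in self.speeds if not any(np.isclose(s, v) for v in SPEEDS)
        ]
        if unknown_speeds:
            raise ConfigurationError(f"unknown speeds: {unknown_speeds}")
        if self.speeds:
            longest = max(self.stride_time[s] for s in self.speeds)
            if self.duration < 3 * longest:
                raise ConfigurationError(
                    f"duration {self.duration}s must cover >= 3 strides "
                    f"({3 * longest:.2f}s at the slowest speed)"
                )

    def gyro_amplitude(self, speed: float) -> float:
        """Base gyro amplitude (deg/s) at full bodyweight; grows with speed."""
        return 150.0 + 150.0 * speed

    def stance_fraction_for(self, speed: float) -> float:
        """Stance share of the stride at the given speed."""
        if isinstance(self.stance_fraction, dict):
            key = min(self.stance_fraction, key=lambda s: abs(s - speed))
            return float(self.stance_fraction[key])
        return float(self.stance_fraction)


@dataclass
class TemplateParams:
    """Shape parameters of one stride's template."""

    stance_fraction: float = 0.6
    zc_fraction: float = 0.0  # phase of the neg->pos gyro crossing (IC lead)
    amplitude: float = 1.0
    ripple: float = 0.25  # force double-hump depth; smaller underwater
    pedestal: float = 0.017  # contact pedestal as a fraction of peak load

    def __post_init__(self) -> None:
        if not 0 < self.stance_fraction < 1:
            raise ConfigurationError("stance_fraction must lie in (0, 1)")


def _gyro_spline(stance_fraction: float) -> CubicSpline:
    u = stance_fraction
    phases, values = [], []
    for p, v in GYRO_CONTROL_POINTS:
        # control phases are stored as fractions of stance (<=1) / swing (>1)
        phases.append(p * u if p <= 1.0 else u + (p - 1.0) * (1.0 - u))
        values.append(v)
    return CubicSpline(phases, values, bc_type="periodic")


#: small constant contact force (N) carried throughout stance. It puts the
#: raw force above the 10 N event threshold from the very first stance
#: sample while keeping the on/off discontinuity tiny, so the 4 Hz
#: zero-phase filter neither rings above threshold in the swing valleys nor
#: drags the detected events away from the true contact instants.
PEDESTAL_N = 12.0

_RAMP = 0.3  # load build-up / release, as a fraction of stance


def _smoothstep(t: np.ndarray) -> np.ndarray:
    # quintic: zero first and second derivatives at both ends, so the force
    # train stays spectrally compact and the 4 Hz filter leaves clean
    # swing-phase valleys
    t = np.clip(t, 0.0, 1.0)
    return t**3 * (10.0 - 15.0 * t + 6.0 * t * t)


def _force_hump(x: np.ndarray, ripple: float) -> np.ndarray:
    """Unit-peak stance load curve on x in [0, 1]: smooth (C1) build-up and
    release ramps around a plateau, modulated into the loading/unloading
    double hump with a mid-stance valley."""
    x = np.asarray(x, dtype=float)
    plateau = _smoothstep(x / _RAMP) * _smoothstep((1.0 - x) / _RAMP)
    shape = plateau * (1.0 + ripple * np.cos(2.0 * np.pi * x))
    # normalize to exactly unit peak on a dense grid (shape-dependent max)
    dense = np.linspace(0.0, 1.0, 2001)
    ref = _smoothstep(dense / _RAMP) * _smoothstep((1.0 - dense) / _RAMP)
    peak = np.max(ref * (1.0 + ripple * np.cos(2.0 * np.pi * dense)))
    return shape / peak


def stride_template(phase, params: TemplateParams) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the stride template at ``phase`` (fractions of one stride).

    Returns ``(gyro, force_fraction)``: the gyro value (amplitude-scaled,
    with its negative-to-positive zero-crossing at phase ``zc_fraction`` and
    its positive-to-negative crossing near the stance/swing boundary), and
    the vertical force as a fraction of the supported peak load (0 through
    swing, unit-peak double hump during stance).
    """
    p = np.asarray(phase, dtype=float) % 1.0
    spline = _gyro_spline(params.stance_fraction)
    gyro = params.amplitude * spline((p - params.zc_fraction) % 1.0)
    u = params.stance_fraction
    force = np.zeros_like(p)
    stance = p < u
    force[stance] = params.pedestal + (1.0 - params.pedestal) * _force_hump(
        p[stance] / u, params.ripple
    )
    if np.isscalar(phase):
        return float(gyro), float(force)
    return gyro, force


def _child_seed(config_seed: int, *parts) -> np.random.SeedSequence:
    tag = "|".join(str(p) for p in parts)
    return np.random.SeedSequence([int(config_seed), zlib.crc32(tag.encode())])


def subject_amplitude(config: SimConfig, subject_id: str) -> float:
    """Deterministic per-subject gyro amplitude multiplier (drawn once)."""
    rng = np.random.default_rng(_child_seed(config.seed, "amp", subject_id))
    z = float(np.clip(rng.standard_normal(), -3.0, 3.0))
    return max(0.5, 1.0 + config.subject_amp_cv * z)


def simulate_recording(
    subject_id: str,
    speed: float,
    condition: str,
    config: SimConfig,
) -> tuple[GaitRecording, EventSet]:
    """Simulate one recording and its exact ground-truth events.

    Strides are concatenated with per-stride durations ~ Normal(mean,
    (jitter_cv x mean)^2) truncated at +-3 SD and per-stride gyro
    amplitudes jittered the same way (amp_jitter_cv); the record opens with a short
    swing lead-in so the first IC is an interior sample. Identical
    (config.seed, subject, speed, condition) gives identical output.
    """
    if condition not in SUPPORT_FRACTION:
        raise ConfigurationError(f"unknown condition {condition!r}")
    speed = float(speed)
    if not any(np.isclose(speed, s) for s in SPEEDS):
        raise ConfigurationError(f"unknown speed {speed}")
    environment = _ENVIRONMENT_OF[condition]
    mean_stride = config.stride_time[min(SPEEDS, key=lambda s: abs(s - speed))]
    if config.duration < 3 * mean_stride:
        raise ConfigurationError("duration too short for 3 strides")

    fs = config.fs
    n_total = int(round(config.duration * fs))
    rng = np.random.default_rng(_child_seed(config.seed, subject_id, speed, condition))
    amp = (
        config.gyro_amplitude(speed)
        * config.amp_scale[condition]
        * subject_amplitude(config, subject_id)
    )
    support_frac = SUPPORT_FRACTION[condition]
    peak_force = (1.0 - support_frac) * config.bodyweight
    ripple = 0.25 if environment == "land" else 0.10
    u = config.stance_fraction_for(speed)
    spline = _gyro_spline(u)
    hump = _force_hump  # alias

    gyro_parts: list[np.ndarray] = []
    force_parts: list[np.ndarray] = []
    ic_list: list[int] = []
    fo_list: list[int] = []

    # swing lead-in: last 20% of a nominal stride (pure swing, zero force)
    n_lead = max(1, int(round(0.2 * mean_stride * fs)))
    lead_phase = 1.0 - (n_lead - np.arange(n_lead)) / (mean_stride * fs)
    gyro_parts.append(amp * spline(np.clip(lead_phase, 0.0, 1.0 - 1e-12)))
    force_parts.append(np.zeros(n_lead))
    pos = n_lead

    while pos < n_total:
        z, za = np.clip(rng.standard_normal(2), -3.0, 3.0)
        dur = mean_stride * (1.0 + config.jitter_cv * float(z))
        stride_amp = amp * (1.0 + config.amp_jitter_cv * float(za))
        n_k = max(6, int(round(dur * fs)))
        n_stance = min(n_k - 1, max(1, int(round(u * n_k))))
        zc = config.ic_lead[environment] / (n_k / fs)
        phases = np.arange(n_k) / n_k
        gyro_parts.append(stride_amp * spline((phases - zc) % 1.0))
        f = np.zeros(n_k)
        x = (np.arange(n_stance) + 1.0) / (n_stance + 1.0)
        hv = hump(x, ripple)
        # renormalize the sampled hump so every stride peaks at exactly
        # (1 - support fraction) x bodyweight regardless of stance length;
        # the pedestal keeps even the first/last stance samples above the
        # 10 N event threshold
        f[:n_stance] = PEDESTAL_N + (peak_force - PEDESTAL_N) * hv / hv.max()
        force_parts.append(f)
        ic_list.append(pos)
        if pos + n_stance < n_total:
            fo_list.append(pos + n_stance)
        pos += n_k

    gyro = np.concatenate(gyro_parts)[:n_total]
    vforce = np.concatenate(force_parts)[:n_total]
    if config.noise_sd > 0:
        gyro = gyro + rng.normal(0.0, config.noise_sd, n_total)
    ic = np.array([i for i in ic_list if i < n_total], dtype=int)
    fo = np.array(fo_list, dtype=int)
    rec = GaitRecording(
        subject_id=subject_id,
        environment=environment,
        support=condition,
        speed=speed,
        fs=fs,
        time=np.arange(n_total) / fs,
        gyro_y=gyro,
        vforce=vforce,
    )
    events = EventSet(ic=ic, fo=fo)
    events.validate(n=n_total)
    return rec, events


def simulate_cohort(config: SimConfig) -> list[tuple[GaitRecording, EventSet]]:
    """Simulate the full subject x speed x condition grid.

    Subject IDs are S01, S02, ...; each subject's amplitude multiplier is
    drawn once and shared across that subject's recordings.
    """
    if config.n_subjects < 1 or not config.speeds or not config.conditions:
        raise ConfigurationError("empty simulation grid")
    out = []
    for i in range(config.n_subjects):
        subject = f"S{i + 1:02d}"
        for speed in config.speeds:
            for condition in config.conditions:
                out.append(simulate_recording(subject, speed, condition, config))
    return out
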