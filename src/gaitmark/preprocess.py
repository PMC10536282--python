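"""Resampling, zero-phase low-pass filtering, and amplitude normalization.

All analysis runs on a 100 Hz grid after 4 Hz low-pass filtering. The filter
is a 4th-order Butterworth applied forward-backward (zero phase): phase
distortion would shift event timing, which is exactly what the classifier
must learn. Each subject's gyro channels are amplitude normalized by the
subject's maximum |filtered gyro| in a reference condition — fastest speed
(1.6 m/s) without bodyweight support on land, or at waist depth underwater —
so the reference recording peaks at exactly 1.

Processing order for a subject's recordings: filter -> extract central
portion -> normalize (the reference scalar is computed on the extracted
portion).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .core import (
    ConfigurationError,
    GaitRecording,
    SamplingError,
    ValidationError,
)

__all__ = [
    "PreprocessParams",
    "resample_to",
    "lowpass",
    "extract_central",
    "normalize_amplitude",
    "preprocess_recording",
]

#: central-portion duration extracted per environment (seconds). On land the
#: central 3 min of a 4 min trial is analysed; underwater the central ~2 min
#: of a 3 min trial. Shorter records keep everything except the filter-edge
#: margin.
CENTRAL_DURATION_S = {"land": 180.0, "water": 120.0}

#: reference condition (support, speed) per environment for normalization.
NORMALIZATION_REFERENCE = {"land": ("none", 1.6), "water": ("waist", 1.6)}


@dataclass
class PreprocessParams:
    target_fs: float = 100.0
    cutoff: float = 4.0
    filter_order: int = 4

    def __post_init__(self) -> None:
        if self.filter_order < 1:
            raise ConfigurationError("filter_order must be >= 1")
        if not 0 < self.cutoff < self.target_fs / 2:
            raise ConfigurationError(
                f"cutoff ({self.cutoff} Hz) must lie below the Nyquist "
                f"frequency of target_fs ({self.target_fs} Hz)"
            )

    @property
    def edge_samples(self) -> int:
        """Samples at each end contaminated by filter edge effects."""
        return self.filter_order * 3


def resample_to(rec: GaitRecording, target_fs: float) -> GaitRecording:
    """Downsample a recording to ``target_fs`` (anti-aliased; identity if
    the rate already matches). Upsampling is refused."""
    if target_fs <= 0:
        raise ConfigurationError("target_fs must be positive")
    if np.isclose(rec.fs, target_fs, rtol=1e-9):
        return rec.copy_with()
    if target_fs > rec.fs:
        raise SamplingError(
            f"refusing to upsample from {rec.fs} Hz to {target_fs} Hz"
        )
    ratio = Fraction(target_fs / rec.fs).limit_denominator(10_000)
    up, down = ratio.numerator, ratio.denominator
    gyro = signal.resample_poly(rec.gyro_y, up, down)
    vforce = np.clip(signal.resample_poly(rec.vforce, up, down), 0.0, None)
    n = len(gyro)
    time = rec.time[0] + np.arange(n) / target_fs
    return rec.copy_with(fs=float(target_fs), time=time, gyro_y=gyro, vforce=vforce)


def lowpass(series, fs: float, cutoff: float = 4.0, order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValidationError("series must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValidationError("series contains non-finite values")
    if not 0 < cutoff < fs / 2:
        raise ConfigurationError(f"cutoff {cutoff} Hz outside (0, fs/2)")
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    padlen = 3 * (2 * order + 1)
    if x.size <= padlen:
        raise ValidationError(
            f"series too short to filter ({x.size} <= {padlen} samples)"
        )
    return signal.sosfiltfilt(sos, x)


def extract_central(
    rec: GaitRecording,
    duration_s: float | None = None,
    edge_samples: int = 12,
) -> GaitRecording:
    """Extract the central ``duration_s`` seconds of a recording.

    Records too short for the requested central window fall back to the full
    record minus ``edge_samples`` at each end (the filter-transient margin).
    """
    if duration_s is None:
        duration_s = CENTRAL_DURATION_S[rec.environment]
    n = len(rec)
    n_target = int(round(duration_s * rec.fs))
    if n - 2 * edge_samples <= n_target:
        lo, hi = edge_samples, n - edge_samples
    else:
        lo = (n - n_target) // 2
        hi = lo + n_target
    if hi - lo < 2:
        raise ValidationError("recording too short for central extraction")
    return rec.copy_with(
        time=rec.time[lo:hi], gyro_y=rec.gyro_y[lo:hi], vforce=rec.vforce[lo:hi]
    )


def _reference_scalar(recs: list[GaitRecording], environment: str) -> float:
    support, speed = NORMALIZATION_REFERENCE[environment]
    refs = [
        r
        for r in recs
        if r.support == support and np.isclose(r.speed, speed, rtol=1e-9)
    ]
    if not refs:
        raise ConfigurationError(
            f"missing normalization reference recording "
            f"({support} @ {speed} m/s, {environment})"
        )
    scalar = max(float(np.max(np.abs(r.gyro_y))) for r in refs)
    if scalar <= 0:
        raise ValidationError("degenerate reference signal (max |gyro| == 0)")
    return scalar


def normalize_amplitude(recs: list[GaitRecording]) -> list[GaitRecording]:
    """Normalize one subject's gyro channels by the reference-condition peak.

    All recordings must belong to the same subject and environment; every
    gyro channel is divided by the subject's max |gyro| in the reference
    condition, so the reference recording's own peak becomes exactly 1.
    """
    if not recs:
        return []
    subjects = {r.subject_id for r in recs}
    environments = {r.environment for r in recs}
    if len(subjects) > 1 or len(environments) > 1:
        raise ConfigurationError(
            "normalize_amplitude expects recordings from one subject and "
            f"one environment (got subjects={subjects}, environments={environments})"
        )
    scalar = _reference_scalar(recs, recs[0].environment)
    return [r.copy_with(gyro_y=r.gyro_y / scalar) for r in recs]


def preprocess_recording(
    rec: GaitRecording,
    params: PreprocessParams | None = None,
    central_duration_s: float | None = None,
    filter_force: bool = False,
) -> GaitRecording:
    """Resample to the target rate, low-pass the gyro channel, extract the
    central portion. Normalization is a per-subject step applied afterwards
    via :func:`normalize_amplitude`.

    The force channel is kept unfiltered by default: ground-truth event
    thresholding at 10 N is far below the band-limitation ripple a 4 Hz
    filter leaves in the swing-phase valleys of a several-hundred-newton
    force train, so filtering the force before thresholding displaces and
    can corrupt the detected events. Pass ``filter_force=True`` to low-pass
    it anyway (e.g. for plotting or export)."""
    if params is None:
        params = PreprocessParams()
    rec = resample_to(rec, params.target_fs)
    gyro = lowpass(rec.gyro_y, rec.fs, params.cutoff, params.filter_order)
    vforce = rec.vforce
    if filter_force:
        vforce = np.clip(
            lowpass(vforce, rec.fs, params.cutoff, params.filter_order), 0.0, None
        )
    rec = rec.copy_with(gyro_y=gyro, vforce=vforce)
    return extract_central(rec, central_duration_s, params.edge_samples)
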