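"""Core domain types and recording I/O.

The package works with single-foot gait time series: sagittal-plane
(mediolateral-axis) foot angular velocity from a gyroscope and a vertical
foot-ground force channel (treadmill force plate on land, summed insole
force underwater). A recording is one subject x condition trial; conditions
combine treadmill speed with a bodyweight-support level, either mechanical
(harness, on land) or hydrostatic (immersion depth, underwater).

Conventions fixed here and used everywhere downstream:

* sample indices are 0-based and refer to the (post-resampling) 100 Hz grid;
* positive gyro-Y is dorsiflexion-direction rotation of the foot;
* raw gyro is in deg/s and dimensionless after amplitude normalization;
* force is in newtons and non-negative.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GaitmarkError",
    "ValidationError",
    "FormatError",
    "SamplingError",
    "ConfigurationError",
    "GaitRecording",
    "EventSet",
    "EvalReport",
    "validate_labels",
    "read_recording",
    "write_recording",
    "LAND_SUPPORTS",
    "WATER_SUPPORTS",
    "SUPPORT_FRACTION",
    "SPEEDS",
    "FEATURE_COLUMNS",
    "CLASSES",
]


class GaitmarkError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(GaitmarkError):
    """A domain invariant is violated."""


class FormatError(ValidationError):
    """A file does not conform to the expected schema."""


class SamplingError(ValidationError):
    """A time vector is not a uniform grid consistent with the stated rate."""


class ConfigurationError(GaitmarkError):
    """A configuration value or combination is invalid."""


LAND_SUPPORTS = ("none", "bws30", "bws50")
WATER_SUPPORTS = ("waist", "chest")

#: effective bodyweight-support fraction per condition. Waist-deep and
#: chest-deep immersion unload roughly 30% and 50% of bodyweight, matching
#: the two mechanical harness levels used on land.
SUPPORT_FRACTION = {
    "none": 0.0,
    "bws30": 0.3,
    "bws50": 0.5,
    "waist": 0.3,
    "chest": 0.5,
}

#: treadmill belt speeds (m/s) used in the study protocol.
SPEEDS = (0.4, 0.8, 1.2, 1.6)

#: fixed column order of the per-sample feature table.
FEATURE_COLUMNS = (
    "filtered_value",
    "rms",
    "skewness",
    "kurtosis",
    "variance",
    "derivative",
    "zero_cross",
)

#: per-sample classes: 0 background, 1 initial-contact boundary, 2 foot-off
#: boundary.
CLASSES = (0, 1, 2)

_TIME_RTOL = 1e-9


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be 1-D, got shape {arr.shape}")
    return arr


@dataclass
class GaitRecording:
    """One subject x condition gait time series.

    Attributes
    ----------
    subject_id : str
        Subject label, e.g. ``"S01"``.
    environment : {"land", "water"}
    support : {"none", "bws30", "bws50"} on land; {"waist", "chest"} in water
        Bodyweight-support condition.
    speed : float
        Treadmill speed in m/s, one of 0.4/0.8/1.2/1.6.
    fs : float
        Sampling rate in Hz.
    time : ndarray
        Seconds; strictly increasing uniform grid with step 1/fs.
    gyro_y : ndarray
        Foot angular velocity about the mediolateral axis (deg/s, or
        dimensionless after normalization). Same length as ``time``.
    vforce : ndarray
        Vertical foot-ground force (N), non-negative, same length as ``time``.
    """

    subject_id: str
    environment: str
    support: str
    speed: float
    fs: float
    time: np.ndarray
    gyro_y: np.ndarray
    vforce: np.ndarray

    def __post_init__(self) -> None:
        self.time = _as_float_array(self.time, "time")
        self.gyro_y = _as_float_array(self.gyro_y, "gyro_y")
        self.vforce = _as_float_array(self.vforce, "vforce")
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.environment not in ("land", "water"):
            raise ValidationError(f"unknown environment {self.environment!r}")
        allowed = LAND_SUPPORTS if self.environment == "land" else WATER_SUPPORTS
        if self.support not in allowed:
            raise ValidationError(
                f"support {self.support!r} invalid for environment "
                f"{self.environment!r} (allowed: {allowed})"
            )
        if not any(math.isclose(self.speed, s, rel_tol=1e-9) for s in SPEEDS):
            raise ValidationError(
                f"speed {self.speed} m/s not one of {SPEEDS}"
            )
        if not (self.fs > 0 and math.isfinite(self.fs)):
            raise ValidationError(f"fs must be positive, got {self.fs}")
        n = len(self.time)
        if len(self.gyro_y) != n or len(self.vforce) != n:
            raise ValidationError(
                "channel length mismatch: "
                f"time={n}, gyro_y={len(self.gyro_y)}, vforce={len(self.vforce)}"
            )
        if n == 0:
            raise ValidationError("recording has no samples")
        if n > 1:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise SamplingError("time must be strictly increasing")
            step = 1.0 / self.fs
            if not np.allclose(dt, step, rtol=_TIME_RTOL, atol=step * _TIME_RTOL):
                raise SamplingError(
                    f"time grid is not uniform at fs={self.fs} Hz"
                )
        if not np.all(np.isfinite(self.vforce)):
            raise ValidationError("vforce contains non-finite values")
        if np.any(self.vforce < 0):
            raise ValidationError("vforce must be non-negative")
        if not np.all(np.isfinite(self.gyro_y)):
            raise ValidationError("gyro_y contains non-finite values")

    # -- conveniences -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        """Record duration in seconds (n samples / fs)."""
        return len(self) / self.fs

    @property
    def condition(self) -> str:
        return f"{self.support}@{self.speed:g}m/s"

    @property
    def recording_id(self) -> str:
        return f"{self.subject_id}|{self.support}|{self.speed:g}"

    def copy_with(self, **kw) -> "GaitRecording":
        return replace(self, **kw)

    def __eq__(self, other) -> bool:  # array-aware equality
        if not isinstance(other, GaitRecording):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.environment == other.environment
            and self.support == other.support
            and self.speed == other.speed
            and self.fs == other.fs
            and np.array_equal(self.time, other.time)
            and np.array_equal(self.gyro_y, other.gyro_y)
            and np.array_equal(self.vforce, other.vforce)
        )


@dataclass
class EventSet:
    """Ordered initial-contact (IC) and foot-off (FO) sample indices."""

    ic: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    fo: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.ic = np.asarray(self.ic, dtype=int).ravel()
        self.fo = np.asarray(self.fo, dtype=int).ravel()

    def validate(self, n: int | None = None, strict_alternation: bool = True) -> None:
        for name, idx in (("ic", self.ic), ("fo", self.fo)):
            if idx.size and np.any(np.diff(idx) <= 0):
                raise ValidationError(f"{name} indices must be strictly increasing")
            if idx.size and idx[0] < 0:
                raise ValidationError(f"{name} indices must be non-negative")
            if n is not None and idx.size and idx[-1] >= n:
                raise ValidationError(
                    f"{name} index {idx[-1]} out of range for length {n}"
                )
        if strict_alternation and self.ic.size + self.fo.size >= 2:
            merged = np.concatenate([self.ic, self.fo])
            kinds = np.concatenate(
                [np.zeros(self.ic.size, int), np.ones(self.fo.size, int)]
            )
            order = np.argsort(merged, kind="stable")
            if np.any(np.diff(merged[order]) == 0):
                raise ValidationError("IC and FO events share a sample index")
            k = kinds[order]
            if np.any(k[1:] == k[:-1]):
                raise ValidationError(
                    "events must alternate between IC and FO"
                )

    def __len__(self) -> int:
        return int(self.ic.size + self.fo.size)

    def shifted(self, offset: int) -> "EventSet":
        return EventSet(ic=self.ic + offset, fo=self.fo + offset)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventSet):
            return NotImplemented
        return np.array_equal(self.ic, other.ic) and np.array_equal(self.fo, other.fo)


def validate_labels(labels, n: int | None = None) -> np.ndarray:
    """Validate a per-sample class sequence over {0, 1, 2}; return int array."""
    arr = np.asarray(labels)
    if arr.ndim != 1:
        raise ValidationError("labels must be 1-D")
    if arr.size and not np.isin(arr, CLASSES).all():
        bad = np.unique(arr[~np.isin(arr, CLASSES)])
        raise ValidationError(f"labels contain values outside {{0,1,2}}: {bad}")
    if n is not None and arr.size != n:
        raise ValidationError(f"label length {arr.size} != expected {n}")
    return arr.astype(int)


@dataclass
class EvalReport:
    """Per-sample classification report.

    ``confusion`` is a 3x3 integer matrix (rows = true class, columns =
    predicted class, classes ordered 0/1/2); precision/recall/f1 are
    one-vs-rest per class with the 0/0 -> 0 convention; ``accuracy`` is
    trace/total. ``accuracy_cv``/``per_fold`` are filled only when 10-fold
    cross-validation within the training pool was requested.
    """

    confusion: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    accuracy: float
    n_samples: int
    accuracy_cv: float | None = None
    per_fold: np.ndarray | None = None

    def validate(self) -> None:
        if self.confusion.shape != (3, 3) or np.any(self.confusion < 0):
            raise ValidationError("confusion must be a non-negative 3x3 matrix")
        if int(self.confusion.sum()) != self.n_samples:
            raise ValidationError("confusion entries must sum to n_samples")
        for name, v in (
            ("precision", self.precision),
            ("recall", self.recall),
            ("f1", self.f1),
        ):
            if np.any((np.asarray(v) < 0) | (np.asarray(v) > 1)):
                raise ValidationError(f"{name} outside [0, 1]")
        if not 0 <= self.accuracy <= 1:
            raise ValidationError("accuracy outside [0, 1]")

    def to_dict(self) -> dict:
        d = {
            "confusion": self.confusion.astype(int).tolist(),
            "per_class": {
                str(c): {
                    "precision": float(self.precision[i]),
                    "recall": float(self.recall[i]),
                    "f1": float(self.f1[i]),
                }
                for i, c in enumerate(CLASSES)
            },
            "accuracy": float(self.accuracy),
            "n_samples": int(self.n_samples),
        }
        if self.accuracy_cv is not None:
            d["accuracy_cv"] = float(self.accuracy_cv)
            d["per_fold"] = [float(a) for a in np.asarray(self.per_fold)]
        return d


# ---------------------------------------------------------------------------
# recording I/O: long-form CSV + JSON (or YAML) metadata sidecar
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ("time", "gyro_y", "vforce")
_META_KEYS = ("subject_id", "environment", "support", "speed_mps", "fs_hz")


def write_recording(rec: GaitRecording, csv_path, meta_path) -> tuple[Path, Path]:
    """Write a recording as CSV (time,gyro_y,vforce) + JSON metadata sidecar.

    Floats are printed with ``repr`` (shortest round-tripping form), so
    ``read_recording`` inverts this bit-for-bit.
    """
    rec.validate()
    csv_path, meta_path = Path(csv_path), Path(meta_path)
    try:
        with open(csv_path, "w", encoding="utf-8") as fh:
            fh.write(",".join(_CSV_COLUMNS) + "\n")
            for t, g, f in zip(
                rec.time.tolist(), rec.gyro_y.tolist(), rec.vforce.tolist()
            ):
                fh.write(f"{t!r},{g!r},{f!r}\n")
        meta = {
            "subject_id": rec.subject_id,
            "environment": rec.environment,
            "support": rec.support,
            "speed_mps": rec.speed,
            "fs_hz": rec.fs,
        }
        with open(meta_path, "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except OSError as exc:
        raise GaitmarkError(f"cannot write recording: {exc}") from exc
    return csv_path, meta_path


def _load_metadata(meta_path: Path) -> dict:
    text = meta_path.read_text(encoding="utf-8")
    if meta_path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        meta = yaml.safe_load(text)
    else:
        try:
            meta = json.loads(text)
        except json.JSONDecodeError:
            import yaml  # JSON is a YAML subset; accept YAML content too

            meta = yaml.safe_load(text)
    if not isinstance(meta, dict):
        raise FormatError(f"metadata in {meta_path} is not a mapping")
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise FormatError(f"metadata missing keys: {missing}")
    return meta


def read_recording(csv_path, meta_path) -> GaitRecording:
    """Read and validate a recording written by :func:`write_recording`."""
    csv_path, meta_path = Path(csv_path), Path(meta_path)
    meta = _load_metadata(meta_path)
    try:
        df = pd.read_csv(csv_path, float_precision="round_trip")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {csv_path}: {exc}") from exc
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{csv_path} missing columns: {missing}")
    return GaitRecording(
        subject_id=str(meta["subject_id"]),
        environment=str(meta["environment"]),
        support=str(meta["support"]),
        speed=float(meta["speed_mps"]),
        fs=float(meta["fs_hz"]),
        time=df["time"].to_numpy(float),
        gyro_y=df["gyro_y"].to_numpy(float),
        vforce=df["vforce"].to_numpy(float),
    )
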