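"""Per-sample features from the filtered, normalized gyro signal.

Each sample of the sagittal-plane foot angular velocity contributes one
feature row: the filtered value itself, four statistics (RMS, skewness,
excess kurtosis, variance) over a centered 5-sample window, the first
derivative, and a binary zero-crossing flag. Windows use reflected padding
at the record edges so the feature table stays aligned 1:1 with the label
vector; moments are population (divide-by-n) moments, and windows with
negligible spread report zero skewness/kurtosis rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .core import FEATURE_COLUMNS, GaitRecording, ValidationError

__all__ = [
    "FeatureParams",
    "windowed_stats",
    "derivative",
    "zero_cross_flags",
    "build_feature_table",
]

#: variance below this is treated as a degenerate (constant) window.
DEGENERATE_VAR = 1e-12


@dataclass
class FeatureParams:
    window: int = 5
    include_value: bool = True
    include_derivative: bool = True
    include_zero_cross: bool = True

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValidationError("window must be odd and >= 3")


def _check_series(series, min_len: int, name: str = "series") -> np.ndarray:
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValidationError(f"{name} must be 1-D")
    if x.size < min_len:
        raise ValidationError(f"{name} length {x.size} < required {min_len}")
    if not np.all(np.isfinite(x)):
        raise ValidationError(f"{name} contains non-finite values")
    return x


def windowed_stats(series, window: int = 5) -> pd.DataFrame:
    """Centered sliding-window RMS, skewness, excess kurtosis and variance.

    Population moments: variance m2 = mean((x-mean)^2), skewness =
    m3 / m2^1.5, kurtosis = m4 / m2^2 - 3 (normal -> 0). Degenerate windows
    (m2 < 1e-12) report skewness 0 and kurtosis 0. Reflected edge padding
    keeps the output length equal to the input length.
    """
    x = _check_series(series, window)
    half = window // 2
    padded = np.pad(x, half, mode="reflect")
    w = sliding_window_view(padded, window)  # (n, window)
    mean = w.mean(axis=1)
    rms = np.sqrt(np.mean(w * w, axis=1))
    d = w - mean[:, None]
    m2 = np.mean(d * d, axis=1)
    m3 = np.mean(d**3, axis=1)
    m4 = np.mean(d**4, axis=1)
    ok = m2 >= DEGENERATE_VAR
    skew = np.zeros_like(m2)
    kurt = np.zeros_like(m2)
    skew[ok] = m3[ok] / m2[ok] ** 1.5
    kurt[ok] = m4[ok] / m2[ok] ** 2 - 3.0
    return pd.DataFrame(
        {"rms": rms, "skewness": skew, "kurtosis": kurt, "variance": m2}
    )


def derivative(series, fs: float) -> np.ndarray:
    """First derivative: central differences inside, one-sided at the ends."""
    x = _check_series(series, 2)
    return np.gradient(x, 1.0 / fs)


def zero_cross_flags(series) -> np.ndarray:
    """Binary flags: 1 where the signal changes sign relative to the
    previous sample (or touches zero from a nonzero value); flag[0] = 0."""
    x = _check_series(series, 1)
    flags = np.zeros(x.size, dtype=int)
    if x.size > 1:
        prev, cur = x[:-1], x[1:]
        flags[1:] = ((prev * cur < 0) | ((cur == 0) & (prev != 0))).astype(int)
    return flags


def build_feature_table(
    rec: GaitRecording, params: FeatureParams | None = None
) -> pd.DataFrame:
    """Assemble the 7-column per-sample feature table for one recording.

    Columns, in fixed order: filtered_value, rms, skewness, kurtosis,
    variance, derivative, zero_cross. Row i corresponds to sample i of the
    (already filtered and normalized) recording.
    """
    if params is None:
        params = FeatureParams()
    g = rec.gyro_y
    stats = windowed_stats(g, params.window)
    table = pd.DataFrame(
        {
            "filtered_value": g if params.include_value else np.zeros_like(g),
            "rms": stats["rms"].to_numpy(),
            "skewness": stats["skewness"].to_numpy(),
            "kurtosis": stats["kurtosis"].to_numpy(),
            "variance": stats["variance"].to_numpy(),
            "derivative": derivative(g, rec.fs)
            if params.include_derivative
            else np.zeros_like(g),
            "zero_cross": zero_cross_flags(g)
            if params.include_zero_cross
            else np.zeros(g.size, dtype=int),
        },
        columns=list(FEATURE_COLUMNS),
    )
    return table
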