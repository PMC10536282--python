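"""Stride-resampled cross-correlation similarity between conditions.

For each pair of bodyweight-support conditions at a given speed, five
consecutive strides are extracted from the middle of each recording,
resampled to a fixed per-speed length (slower speeds have longer strides,
hence more samples), and compared with the zero-lag Pearson correlation
coefficient. Ten iterations slide the five-stride window one cycle at a
time; the reported coefficient is the average over iterations (and over
subjects present in both conditions). Segments are aligned by stride index
— both start at an IC — with no additional phase alignment or lag search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ConfigurationError, EventSet, GaitRecording, ValidationError
from .corpus import Corpus

__all__ = [
    "SimilarityParams",
    "extract_stride_segment",
    "resample_segment",
    "pairwise_similarity",
    "similarity_matrix",
    "TABLE_PAIRS",
]

#: the eight condition pairs of the similarity table.
TABLE_PAIRS = (
    ("none", "bws30"),
    ("none", "bws50"),
    ("none", "waist"),
    ("none", "chest"),
    ("bws30", "waist"),
    ("bws50", "chest"),
    ("bws30", "bws50"),
    ("waist", "chest"),
)


def _default_resample_len() -> dict:
    return {0.4: 800, 0.8: 600, 1.2: 600, 1.6: 400}


@dataclass
class SimilarityParams:
    n_strides: int = 5
    resample_len: dict = field(default_factory=_default_resample_len)
    n_iterations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strides < 2:
            raise ConfigurationError("n_strides must be >= 2")
        if any(v < 2 for v in self.resample_len.values()):
            raise ConfigurationError("resample lengths must be >= 2")
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")


def extract_stride_segment(
    rec: GaitRecording, events: EventSet, n_strides: int, offset: int
) -> np.ndarray:
    """Gyro samples spanning ``n_strides`` consecutive IC-to-IC cycles,
    starting ``offset`` cycles into the record."""
    ic = events.ic
    if offset < 0:
        raise ValidationError("offset must be >= 0")
    if ic.size < offset + n_strides + 1:
        raise ValidationError(
            f"recording holds only {max(ic.size - 1, 0)} full cycles; "
            f"need {offset + n_strides}"
        )
    start, stop = int(ic[offset]), int(ic[offset + n_strides])
    return rec.gyro_y[start:stop]


def resample_segment(segment, target_len: int) -> np.ndarray:
    """Linear-interpolation resampling onto ``target_len`` uniformly spaced
    points spanning the segment (endpoints preserved)."""
    seg = np.asarray(segment, dtype=float)
    if seg.size < 2:
        raise ValidationError("segment must hold at least 2 samples")
    if target_len < 2:
        raise ConfigurationError("target_len must be >= 2")
    old = np.linspace(0.0, 1.0, seg.size)
    new = np.linspace(0.0, 1.0, target_len)
    return np.interp(new, old, seg)


def _mid_offset(n_cycles: int, n_strides: int, n_iterations: int) -> int:
    """First cycle of the iteration-0 window, centred in the record."""
    span = n_strides + n_iterations - 1
    return max(0, (n_cycles - span) // 2)


def _resample_len_for(params: SimilarityParams, speed: float) -> int:
    for s, length in params.resample_len.items():
        if np.isclose(s, speed):
            return int(length)
    raise ConfigurationError(f"no resample length configured for speed {speed}")


def _recordings_at(corpus: Corpus, support: str, speed: float):
    out = {}
    for rid, rec in corpus.recordings.items():
        if rec.support == support and np.isclose(rec.speed, speed):
            out[rec.subject_id] = (rec, corpus.events[rid])
    return out


def pairwise_similarity(
    corpus: Corpus,
    pair: tuple[str, str],
    speed: float,
    params: SimilarityParams | None = None,
) -> float:
    """Mean zero-lag Pearson correlation between two conditions at a speed.

    Iteration k compares the five-stride windows starting k cycles after the
    first mid-record cycle of each recording; coefficients are averaged over
    iterations and over the subjects present in both conditions.
    """
    params = params or SimilarityParams()
    cond_a, cond_b = pair
    recs_a = _recordings_at(corpus, cond_a, speed)
    recs_b = _recordings_at(corpus, cond_b, speed)
    if not recs_a or not recs_b:
        raise ConfigurationError(
            f"conditions {pair} at {speed} m/s not both present in corpus"
        )
    target_len = _resample_len_for(params, speed)
    coeffs = []
    shared = sorted(set(recs_a) & set(recs_b))
    if shared:  # same-subject comparison where the cohorts overlap
        subject_pairs = [(s, s) for s in shared]
    else:  # disjoint cohorts (e.g. land vs water subjects): all crossings
        subject_pairs = [(a, b) for a in sorted(recs_a) for b in sorted(recs_b)]
    for sa, sb in subject_pairs:
        rec_a, ev_a = recs_a[sa]
        rec_b, ev_b = recs_b[sb]
        base_a = _mid_offset(ev_a.ic.size - 1, params.n_strides, params.n_iterations)
        base_b = _mid_offset(ev_b.ic.size - 1, params.n_strides, params.n_iterations)
        for k in range(params.n_iterations):
            seg_a = resample_segment(
                extract_stride_segment(rec_a, ev_a, params.n_strides, base_a + k),
                target_len,
            )
            seg_b = resample_segment(
                extract_stride_segment(rec_b, ev_b, params.n_strides, base_b + k),
                target_len,
            )
            coeffs.append(float(np.corrcoef(seg_a, seg_b)[0, 1]))
    return float(np.mean(coeffs))


def similarity_matrix(
    corpus: Corpus,
    pairs: tuple = TABLE_PAIRS,
    speeds: tuple | None = None,
    params: SimilarityParams | None = None,
) -> pd.DataFrame:
    """Pairwise-correlation table: one row per condition pair, one column
    per speed, plus row/column averages."""
    params = params or SimilarityParams()
    if speeds is None:
        speeds = tuple(
            sorted({float(r.speed) for r in corpus.recordings.values()})
        )
    rows = {}
    for pair in pairs:
        label = f"{pair[0]} vs {pair[1]}"
        rows[label] = [
            pairwise_similarity(corpus, pair, speed, params) for speed in speeds
        ]
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"{s:g} m/s" for s in speeds]
    )
    table["average"] = table.mean(axis=1)
    table.loc["average"] = table.mean(axis=0)
    return table
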