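"""Corpus assembly: preprocessed recordings -> aligned feature/label frames.

A :class:`Corpus` bundles everything the classification and similarity
analyses need: one long per-sample frame (features + class label + condition
metadata + gait-cycle id), the ground-truth event set per recording, and the
preprocessed recordings themselves. Ground truth here means events detected
by the 10 N force threshold on the filtered force channel — the same
definition the classifier is trained to reproduce from the gyro signal.

Gait cycles span IC-to-next-IC; samples before the first IC are assigned to
the first cycle and samples after the last IC to the last, so cycles are
never split across a train/test boundary.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import EventSet, FEATURE_COLUMNS, GaitRecording
from .events import AugmentParams, FORCE_THRESHOLD_N, build_labels, detect_threshold_events
from .features import FeatureParams, build_feature_table
from .preprocess import PreprocessParams, normalize_amplitude, preprocess_recording

__all__ = ["Corpus", "prepare_corpus"]

META_COLUMNS = (
    "recording_id",
    "subject",
    "environment",
    "support",
    "speed",
    "cycle_id",
    "sample_idx",
    "label",
)


@dataclass
class Corpus:
    """Per-sample frame plus per-recording events and signals."""

    frames: pd.DataFrame
    events: dict[str, EventSet] = field(default_factory=dict)
    recordings: dict[str, GaitRecording] = field(default_factory=dict)
    fs: float = 100.0

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_cycles(self) -> int:
        return int(self.frames["cycle_id"].nunique())

    def subset(self, mask) -> pd.DataFrame:
        return self.frames.loc[mask]


def _cycle_index(n: int, ic: np.ndarray) -> np.ndarray:
    """Map each sample to its IC-to-IC cycle; edge spans join the nearest
    full cycle."""
    if ic.size < 2:
        return np.zeros(n, dtype=np.int32)
    idx = np.searchsorted(ic, np.arange(n), side="right") - 1
    return np.clip(idx, 0, ic.size - 2).astype(np.int32)


def prepare_corpus(
    recordings: list[GaitRecording],
    pre: PreprocessParams | None = None,
    augment: AugmentParams | None = None,
    feat: FeatureParams | None = None,
    central_duration_s: float | None = None,
    threshold: float = FORCE_THRESHOLD_N,
) -> Corpus:
    """Preprocess, label and featurize a set of recordings into a corpus.

    Per subject x environment group: filter each recording, extract the
    central portion, then amplitude-normalize the group by its reference
    condition. Events are detected on the filtered force, labels built with
    boundary augmentation, features computed from the normalized gyro.
    """
    pre = pre or PreprocessParams()
    augment = augment or AugmentParams()
    feat = feat or FeatureParams()

    groups: dict[tuple, list[GaitRecording]] = defaultdict(list)
    for rec in recordings:
        processed = preprocess_recording(rec, pre, central_duration_s)
        groups[(rec.subject_id, rec.environment)].append(processed)

    pieces: list[pd.DataFrame] = []
    events_by_id: dict[str, EventSet] = {}
    recs_by_id: dict[str, GaitRecording] = {}
    cycle_offset = 0
    for key in sorted(groups):
        for rec in normalize_amplitude(groups[key]):
            rid = rec.recording_id
            n = len(rec)
            events = detect_threshold_events(rec.vforce, threshold, rec.fs)
            labels = build_labels(n, events, augment)
            table = build_feature_table(rec, feat)
            table["recording_id"] = rid
            table["subject"] = rec.subject_id
            table["environment"] = rec.environment
            table["support"] = rec.support
            table["speed"] = rec.speed
            table["cycle_id"] = _cycle_index(n, events.ic) + cycle_offset
            table["sample_idx"] = np.arange(n, dtype=np.int32)
            table["label"] = labels.astype(np.int8)
            cycle_offset = int(table["cycle_id"].max()) + 1
            pieces.append(table)
            events_by_id[rid] = events
            recs_by_id[rid] = rec
    if not pieces:
        frames = pd.DataFrame(columns=list(FEATURE_COLUMNS) + list(META_COLUMNS))
    else:
        frames = pd.concat(pieces, ignore_index=True)
        for col in ("recording_id", "subject", "environment", "support"):
            frames[col] = frames[col].astype("category")
    return Corpus(frames=frames, events=events_by_id, recordings=recs_by_id, fs=pre.target_fs)
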