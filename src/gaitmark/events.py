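"""Ground-truth event detection, class labeling, and label->event conversion.

Ground-truth gait events are defined from the vertical force channel: initial
contact (IC) is the instant the force first exceeds 10 N, foot off (FO) the
instant it falls back below 10 N. Per-sample class labels code IC as 1, FO as
2 and everything else as 0; to mitigate the extreme class imbalance each
single-sample event is augmented to a 10-sample boundary window. A trained
classifier's per-sample predictions are converted back to discrete events by
taking the median index of each sufficiently long predicted run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EventSet, ValidationError, validate_labels

__all__ = [
    "AugmentParams",
    "detect_threshold_events",
    "build_labels",
    "predictions_to_events",
    "timing_errors",
    "TimingResult",
]

#: default force threshold (newtons) defining foot-ground contact.
FORCE_THRESHOLD_N = 10.0

#: minimum separation between accepted same-type events. The fastest
#: plausible stride is far longer than 0.25 s, so anything closer is chatter
#: around the threshold.
REFRACTORY_S = 0.25


@dataclass
class AugmentParams:
    """Boundary-augmentation settings.

    ``width`` samples carry the event's class, at ``offsets`` relative to the
    event sample. "Ten points centered" with an even width is ambiguous; the
    window is placed at offsets -width//2 ... width - width//2 - 1 (i.e.
    -5...+4 for the default), which keeps the event sample inside the window.
    """

    width: int = 10

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValidationError("augmentation width must be >= 1")

    @property
    def offsets(self) -> range:
        return range(-(self.width // 2), self.width - self.width // 2)


def detect_threshold_events(
    vforce,
    threshold: float = FORCE_THRESHOLD_N,
    fs: float = 100.0,
    refractory_s: float = REFRACTORY_S,
) -> EventSet:
    """Detect IC/FO events as upward/downward crossings of a force threshold.

    IC is the first index ``i`` with ``vforce[i] > threshold`` and
    ``vforce[i-1] <= threshold``; FO the first index with the reverse
    crossing. Crossings closer than ``refractory_s`` to the previously
    accepted event of the same type are discarded, and accepted events must
    alternate IC/FO.
    """
    v = np.asarray(vforce, dtype=float)
    if v.ndim != 1:
        raise ValidationError("vforce must be 1-D")
    if v.size == 0:
        return EventSet()
    if not np.all(np.isfinite(v)):
        raise ValidationError("vforce contains non-finite values")
    if np.any(v < 0):
        raise ValidationError("vforce must be non-negative")

    up = np.flatnonzero((v[1:] > threshold) & (v[:-1] <= threshold)) + 1
    down = np.flatnonzero((v[1:] < threshold) & (v[:-1] >= threshold)) + 1
    crossings = sorted(
        [(int(i), "ic") for i in up] + [(int(i), "fo") for i in down]
    )
    gap = int(round(refractory_s * fs))

    ic: list[int] = []
    fo: list[int] = []
    last_kind: str | None = None
    for idx, kind in crossings:
        prev_same = ic if kind == "ic" else fo
        if prev_same and idx - prev_same[-1] < gap:
            continue  # chatter near the threshold
        if kind == last_kind:
            continue  # alternation enforced
        prev_same.append(idx)
        last_kind = kind
    return EventSet(ic=np.array(ic, int), fo=np.array(fo, int))


def build_labels(n: int, events: EventSet, params: AugmentParams | None = None) -> np.ndarray:
    """Build the per-sample class vector with boundary augmentation.

    Labels start at 0 everywhere; each IC event writes class 1 and each FO
    event class 2 over its augmentation window, clipped at the record
    boundaries. Where an IC and an FO window overlap (possible at very short
    stance), the later-in-time event wins on the contested samples, which
    preserves the upcoming transition.
    """
    if params is None:
        params = AugmentParams()
    events.validate(n=n, strict_alternation=False)
    labels = np.zeros(n, dtype=int)
    tagged = sorted(
        [(int(i), 1) for i in events.ic] + [(int(j), 2) for j in events.fo]
    )
    lo_off, hi_off = params.offsets[0], params.offsets[-1]
    for idx, cls in tagged:  # ascending order: later events overwrite earlier
        lo = max(0, idx + lo_off)
        hi = min(n, idx + hi_off + 1)
        labels[lo:hi] = cls
    return labels


def _runs(labels: np.ndarray, cls: int) -> list[tuple[int, int]]:
    """Maximal runs of ``cls`` as (start, stop) half-open pairs."""
    mask = labels == cls
    if not mask.any():
        return []
    edges = np.flatnonzero(np.diff(mask.astype(int)))
    starts = list(edges[mask[edges + 1]] + 1)
    stops = list(edges[~mask[edges + 1]] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(labels))
    return list(zip(starts, stops))


def predictions_to_events(
    pred_labels,
    fs: float = 100.0,
    min_run: int = 3,
    merge_s: float = 0.25,
) -> EventSet:
    """Convert per-sample predictions back to discrete IC/FO events.

    Runs of the same class closer than ``merge_s`` are merged, then each
    merged run with at least ``min_run`` member samples yields one event at
    the median member index (lower of the two middles for even counts).
    Isolated one- or two-sample predictions are treated as noise.
    """
    labels = validate_labels(pred_labels)
    merge_gap = int(round(merge_s * fs))
    out: dict[int, list[int]] = {1: [], 2: []}
    for cls in (1, 2):
        runs = _runs(labels, cls)
        merged: list[list[tuple[int, int]]] = []
        for run in runs:
            if merged and run[0] - merged[-1][-1][1] < merge_gap:
                merged[-1].append(run)
            else:
                merged.append([run])
        for group in merged:
            members = np.concatenate([np.arange(a, b) for a, b in group])
            if members.size >= min_run:
                out[cls].append(int(members[(members.size - 1) // 2]))
    return EventSet(ic=np.array(sorted(out[1]), int), fo=np.array(sorted(out[2]), int))


@dataclass
class TimingResult:
    """Signed event-timing errors (seconds) and match/miss/spurious counts."""

    errors_s: np.ndarray = field(default_factory=lambda: np.array([]))
    n_matched: int = 0
    n_missed: int = 0
    n_spurious: int = 0

    @property
    def mean_abs_error_s(self) -> float:
        return float(np.mean(np.abs(self.errors_s))) if self.errors_s.size else float("nan")

    def fraction_within(self, tol_s: float) -> float:
        """Fraction of truth events matched within ``tol_s`` seconds."""
        total = self.n_matched + self.n_missed
        if total == 0:
            return float("nan")
        return float(np.sum(np.abs(self.errors_s) <= tol_s) / total)


def _match_one_type(pred: np.ndarray, truth: np.ndarray, fs: float, tol: float):
    """Greedy nearest matching of one event type within ``tol`` seconds."""
    if pred.size == 0 or truth.size == 0:
        return np.array([]), 0, int(truth.size), int(pred.size)
    tol_samples = tol * fs
    pairs = []
    for i, p in enumerate(pred):
        for j, t in enumerate(truth):
            d = abs(p - t)
            if d <= tol_samples:
                pairs.append((d, i, j))
    pairs.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    errors = []
    for _, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        errors.append((pred[i] - truth[j]) / fs)
    return (
        np.array(errors, float),
        len(errors),
        int(truth.size - len(used_t)),
        int(pred.size - len(used_p)),
    )


def timing_errors(
    predicted: EventSet,
    truth: EventSet,
    fs: float = 100.0,
    tol_s: float = 0.1,
) -> TimingResult:
    """Match predicted to truth events (per type, greedy nearest within tol).

    Unmatched truth events count as misses, unmatched predictions as
    spurious; signed errors are (predicted - truth) in seconds.
    """
    res = TimingResult()
    errs = []
    for kind in ("ic", "fo"):
        e, m, miss, spur = _match_one_type(
            getattr(predicted, kind), getattr(truth, kind), fs, tol_s
        )
        errs.append(e)
        res.n_matched += m
        res.n_missed += miss
        res.n_spurious += spur
    res.errors_s = np.concatenate(errs) if errs else np.array([])
    return res
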