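"""Random-forest gait-event classification under four transfer designs.

The classifier assigns every sample of the gyro feature stream to background
(0), initial-contact boundary (1) or foot-off boundary (2), using a
100-tree random forest with unlimited depth. Four train/test designs probe
how the learned mapping transfers across bodyweight-support conditions:

``A``  train on 80% of the no-BWS land gait cycles, predict all BWS land data;
``B``  train on 10 of 12 land-BWS subjects, test the 2 held-out subjects;
``C``  train on 80% of the land-BWS cycles, predict all underwater data;
``D``  train on 2 of 3 underwater subjects, test the held-out subject.

Splits operate on whole gait cycles (or whole subjects), never raw samples,
so a boundary-label window can never straddle the train/test cut.

``GaitEventModel`` / ``GaitEventResults`` present this as a fitted-model API:
build the model from a :class:`~gaitmark.corpus.Corpus`, call ``fit()``, and
read metrics, event-timing diagnostics and a ``summary()`` table off the
result. The functional helpers (``split_by_cycles``, ``train_forest``,
``predict``, ``confusion_and_metrics``, ``cross_validate_accuracy``,
``run_design``) expose the individual stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .core import (
    CLASSES,
    ConfigurationError,
    EvalReport,
    FEATURE_COLUMNS,
    ValidationError,
)
from .corpus import Corpus
from .events import TimingResult, predictions_to_events, timing_errors

__all__ = [
    "SplitSpec",
    "ForestParams",
    "split_by_cycles",
    "split_cycle_pool",
    "train_forest",
    "predict",
    "confusion_and_metrics",
    "cross_validate_accuracy",
    "GaitEventModel",
    "GaitEventResults",
    "run_design",
]

DESIGNS = {
    "A": "train 80% of no-BWS land cycles; test 100% of BWS land data",
    "B": "train land-BWS data from all but the held-out subjects; test those subjects",
    "C": "train 80% of land-BWS cycles; test 100% of underwater data",
    "D": "train underwater data from all but the held-out subject; test that subject",
}


@dataclass
class SplitSpec:
    """Train/test partition settings for one design."""

    design: str = "A"
    train_fraction: float = 0.8
    held_out_subjects: tuple | None = None  # designs B/D; default: last 2 / last 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ConfigurationError(f"unknown design {self.design!r}")
        if not 0 < self.train_fraction < 1:
            raise ConfigurationError("train_fraction must lie in (0, 1)")


@dataclass
class ForestParams:
    n_trees: int = 100
    max_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")


def _pool_masks(frames: pd.DataFrame, design: str):
    land = frames["environment"] == "land"
    nobws = land & (frames["support"] == "none")
    bws_land = land & frames["support"].isin(["bws30", "bws50"])
    water = frames["environment"] == "water"
    if design == "A":
        return nobws, bws_land
    if design == "B":
        return bws_land, None
    if design == "C":
        return bws_land, water
    return water, None  # D


def split_cycle_pool(pool: pd.DataFrame, fraction: float, seed: int):
    """Shuffle whole gait cycles with the given seed and split the pool into
    (train, rest) with ceil(fraction x n_cycles) cycles in train."""
    ids = np.sort(pool["cycle_id"].unique())
    if ids.size < 5:
        raise ValidationError(
            f"too few gait cycles to split ({ids.size} < 5)"
        )
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(ids)
    n_train = math.ceil(fraction * ids.size)
    train_ids = set(shuffled[:n_train].tolist())
    in_train = pool["cycle_id"].isin(train_ids)
    return pool.loc[in_train], pool.loc[~in_train]


def _split_subjects(pool: pd.DataFrame, held_out: tuple | None, n_default: int):
    subjects = sorted(pool["subject"].unique())
    if held_out is None:
        held_out = tuple(subjects[-n_default:])
    unknown = [s for s in held_out if s not in subjects]
    if unknown:
        raise ConfigurationError(f"held-out subjects not in corpus: {unknown}")
    test_mask = pool["subject"].isin(list(held_out))
    return pool.loc[~test_mask], pool.loc[test_mask]


def split_by_cycles(corpus: Corpus, spec: SplitSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition the corpus into train/test frames for the given design.

    Designs A and C shuffle whole gait cycles of the training pool with the
    spec seed and keep the first ceil(train_fraction x n) cycles; their test
    side is the full transfer corpus (all BWS land / all underwater data).
    Designs B and D hold out whole subjects. No sample ever appears on both
    sides.
    """
    frames = corpus.frames
    pool_mask, test_mask = _pool_masks(frames, spec.design)
    pool = frames.loc[pool_mask]
    if pool.empty:
        raise ConfigurationError(
            f"corpus lacks the training conditions for design {spec.design}"
        )
    if spec.design in ("A", "C"):
        train, _ = split_cycle_pool(pool, spec.train_fraction, spec.seed)
        test = frames.loc[test_mask]
        if test.empty:
            raise ConfigurationError(
                f"corpus lacks the test conditions for design {spec.design}"
            )
    else:
        n_default = 2 if spec.design == "B" else 1
        train, test = _split_subjects(pool, spec.held_out_subjects, n_default)
        if train.empty or test.empty:
            raise ConfigurationError(
                f"design {spec.design} needs at least "
                f"{n_default + 1} subjects in its pool"
            )
    return train, test


def train_forest(
    features: pd.DataFrame, labels, params: ForestParams | None = None
) -> RandomForestClassifier:
    """Fit the 3-class random forest (100 trees, unlimited depth)."""
    params = params or ForestParams()
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValidationError("training labels contain a single class")
    model = RandomForestClassifier(
        n_estimators=params.n_trees,
        max_depth=params.max_depth,
        random_state=params.seed,
        n_jobs=1,
    )
    model.fit(features[list(FEATURE_COLUMNS)], y)
    return model


def predict(model: RandomForestClassifier, features: pd.DataFrame) -> np.ndarray:
    """Per-sample class predictions; schema must match training."""
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise ValidationError(f"feature table missing columns: {missing}")
    if len(features) == 0:
        return np.array([], dtype=int)
    return model.predict(features[list(FEATURE_COLUMNS)]).astype(int)


def confusion_and_metrics(y_true, y_pred) -> EvalReport:
    """3x3 confusion matrix plus per-class one-vs-rest precision/recall/F1
    (0/0 -> 0) and overall accuracy (trace / total)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError("label/prediction length mismatch")
    conf = confusion_matrix(y_true, y_pred, labels=list(CLASSES))
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=list(CLASSES), zero_division=0
    )
    total = int(conf.sum())
    acc = float(np.trace(conf) / total) if total else 0.0
    report = EvalReport(
        confusion=conf,
        precision=prec,
        recall=rec,
        f1=f1,
        accuracy=acc,
        n_samples=total,
    )
    report.validate()
    return report


def cross_validate_accuracy(
    pool: pd.DataFrame,
    params: ForestParams | None = None,
    k: int = 10,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """k-fold cross-validated accuracy with folds that partition whole gait
    cycles (fold sizes differ by at most one cycle)."""
    params = params or ForestParams()
    ids = np.sort(pool["cycle_id"].unique())
    if k > ids.size:
        raise ConfigurationError(f"k={k} exceeds the {ids.size} available cycles")
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(ids), k)
    accs = []
    for fold_ids in folds:
        test_mask = pool["cycle_id"].isin(set(fold_ids.tolist()))
        train, test = pool.loc[~test_mask], pool.loc[test_mask]
        model = train_forest(train, train["label"], params)
        y_hat = predict(model, test)
        accs.append(float(np.mean(y_hat == test["label"].to_numpy())))
    per_fold = np.array(accs)
    return float(per_fold.mean()), per_fold


class GaitEventModel:
    """Random-forest gait-event detector bound to a corpus and a design.

    Parameters
    ----------
    corpus : Corpus
        Preprocessed, labeled and featurized recordings.
    design : {"A", "B", "C", "D"}
        Transfer design (see module docstring).
    split, forest : SplitSpec, ForestParams, optional
        Partition and forest settings; the design on ``split`` is overridden
        by ``design``.
    """

    def __init__(
        self,
        corpus: Corpus,
        design: str = "A",
        split: SplitSpec | None = None,
        forest: ForestParams | None = None,
    ) -> None:
        self.corpus = corpus
        self.split = split or SplitSpec(design=design)
        self.split.design = design
        if design not in DESIGNS:
            raise ConfigurationError(f"unknown design {design!r}")
        self.design = design
        self.forest = forest or ForestParams()

    def fit(
        self,
        cv_folds: int | None = None,
        permute_train_labels: int | None = None,
    ) -> "GaitEventResults":
        """Split, train, predict the design's test corpus and score it.

        ``cv_folds`` additionally runs cycle-level cross-validation within
        the training pool (k extra forest fits). ``permute_train_labels`` is
        a leakage diagnostic: it shuffles the training labels with the given
        seed before fitting, which must destroy event-class performance.
        """
        train, test = split_by_cycles(self.corpus, self.split)
        y_train = train["label"].to_numpy()
        if permute_train_labels is not None:
            y_train = np.random.default_rng(permute_train_labels).permutation(y_train)
        model = train_forest(train, y_train, self.forest)
        y_pred = predict(model, test)
        report = confusion_and_metrics(test["label"].to_numpy(), y_pred)
        if cv_folds:
            cv_mean, per_fold = cross_validate_accuracy(
                train.assign(label=y_train), self.forest, cv_folds, self.split.seed
            )
            report.accuracy_cv = cv_mean
            report.per_fold = per_fold
        timing = self._event_timing(test, y_pred)
        return GaitEventResults(
            design=self.design,
            report=report,
            timing=timing,
            n_train=len(train),
            n_test=len(test),
            classifier=model,
            test_predictions=y_pred,
        )

    def _event_timing(self, test: pd.DataFrame, y_pred: np.ndarray) -> TimingResult:
        """Convert per-sample predictions to events per test recording and
        compare against the threshold-detected ground truth."""
        total = TimingResult()
        errors = []
        pred_series = pd.Series(y_pred, index=test.index)
        for rid, group in test.groupby("recording_id", observed=True):
            order = group["sample_idx"].to_numpy().argsort()
            labels = pred_series.loc[group.index].to_numpy()[order]
            pred_events = predictions_to_events(labels, fs=self.corpus.fs)
            truth = self.corpus.events[str(rid)]
            res = timing_errors(pred_events, truth, fs=self.corpus.fs)
            errors.append(res.errors_s)
            total.n_matched += res.n_matched
            total.n_missed += res.n_missed
            total.n_spurious += res.n_spurious
        total.errors_s = np.concatenate(errors) if errors else np.array([])
        return total


@dataclass
class GaitEventResults:
    """Fit result: per-sample metrics plus event-level timing diagnostics."""

    design: str
    report: EvalReport
    timing: TimingResult
    n_train: int
    n_test: int
    classifier: RandomForestClassifier | None = None
    test_predictions: np.ndarray = field(default_factory=lambda: np.array([], int))

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "description": DESIGNS[self.design],
            "n_train": int(self.n_train),
            "n_test": int(self.n_test),
            **self.report.to_dict(),
            "event_timing": {
                "mean_abs_error_s": self.timing.mean_abs_error_s,
                "n_matched": self.timing.n_matched,
                "misses": self.timing.n_missed,
                "spurious": self.timing.n_spurious,
                "fraction_within_50ms": self.timing.fraction_within(0.05),
            },
        }

    def summary(self) -> str:
        r = self.report
        lines = [
            f"Gait event detection — design {self.design}",
            f"  {DESIGNS[self.design]}",
            f"  train samples: {self.n_train:>9d}    test samples: {self.n_test:>9d}",
            f"  per-sample accuracy: {r.accuracy:.3f}"
            + (f"    CV accuracy: {r.accuracy_cv:.3f}" if r.accuracy_cv is not None else ""),
            "  class      precision  recall   F1",
        ]
        names = {0: "background", 1: "IC", 2: "FO"}
        for i, c in enumerate(CLASSES):
            lines.append(
                f"  {names[c]:<10s} {r.precision[i]:>8.3f} {r.recall[i]:>7.3f} {r.f1[i]:>6.3f}"
            )
        t = self.timing
        lines.append(
            f"  events: {t.n_matched} matched / {t.n_missed} missed / "
            f"{t.n_spurious} spurious; MAE "
            + (f"{t.mean_abs_error_s * 1000:.1f} ms" if t.n_matched else "n/a")
        )
        return "\n".join(lines)


def run_design(
    corpus: Corpus,
    design: str,
    split_seed: int = 0,
    forest_seed: int = 0,
    held_out_subjects: tuple | None = None,
    cv_folds: int | None = None,
) -> GaitEventResults:
    """One-call execution of a transfer design: split -> train -> predict ->
    metrics -> event timing."""
    spec = SplitSpec(
        design=design, seed=split_seed, held_out_subjects=held_out_subjects
    )
    model = GaitEventModel(
        corpus, design=design, split=spec, forest=ForestParams(seed=forest_seed)
    )
    return model.fit(cv_folds=cv_folds)
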