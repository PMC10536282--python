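"""Splits, forest training, metrics and cross-validation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gaitmark.classify import (
    ForestParams,
    GaitEventModel,
    SplitSpec,
    confusion_and_metrics,
    cross_validate_accuracy,
    predict,
    run_design,
    split_by_cycles,
    split_cycle_pool,
    train_forest,
)
from gaitmark.core import ConfigurationError, FEATURE_COLUMNS, ValidationError


def toy_frame(n_cycles=10, per_cycle=20, seed=0):
    """Separable toy: the class is a bucket of one feature column."""
    rng = np.random.default_rng(seed)
    n = n_cycles * per_cycle
    df = pd.DataFrame(rng.normal(0, 1, (n, len(FEATURE_COLUMNS))),
                      columns=list(FEATURE_COLUMNS))
    df["label"] = np.select(
        [df["filtered_value"] > 0.8, df["filtered_value"] < -0.8], [1, 2], 0
    )
    df["cycle_id"] = np.repeat(np.arange(n_cycles), per_cycle)
    return df


class TestSplits:
    def test_cycle_split_uses_ceiling(self):
        train, rest = split_cycle_pool(toy_frame(10), 0.8, 0)
        assert train["cycle_id"].nunique() == 8
        assert rest["cycle_id"].nunique() == 2

    def test_cycle_split_deterministic(self):
        df = toy_frame(12)
        a = split_cycle_pool(df, 0.8, 7)[0]
        b = split_cycle_pool(df, 0.8, 7)[0]
        assert a.index.equals(b.index)

    def test_too_few_cycles_rejected(self):
        with pytest.raises(ValidationError):
            split_cycle_pool(toy_frame(4), 0.8, 0)

    def test_design_b_holds_out_subjects(self, small_land_corpus):
        spec = SplitSpec(design="B", held_out_subjects=("S03",))
        train, test = split_by_cycles(small_land_corpus, spec)
        assert "S03" not in set(train["subject"])
        assert set(test["subject"]) == {"S03"}
        assert not set(train.index) & set(test.index)

    def test_unknown_held_out_subject_rejected(self, small_land_corpus):
        spec = SplitSpec(design="B", held_out_subjects=("S99",))
        with pytest.raises(ConfigurationError):
            split_by_cycles(small_land_corpus, spec)

    def test_design_a_train_and_test_disjoint(self, small_land_corpus):
        train, test = split_by_cycles(small_land_corpus, SplitSpec(design="A"))
        assert set(train["support"]) == {"none"}
        assert set(test["support"]) == {"bws30", "bws50"}
        assert not set(train["cycle_id"]) & set(test["cycle_id"])

    def test_missing_environment_rejected(self, small_land_corpus):
        with pytest.raises(ConfigurationError):
            split_by_cycles(small_land_corpus, SplitSpec(design="D"))


class TestForest:
    def test_memorizes_separable_toy(self):
        df = toy_frame()
        model = train_forest(df, df["label"], ForestParams(seed=0))
        assert np.mean(predict(model, df) == df["label"]) == 1.0

    def test_deterministic_given_seed(self):
        df = toy_frame()
        probe = toy_frame(seed=99)
        a = predict(train_forest(df, df["label"], ForestParams(seed=3)), probe)
        b = predict(train_forest(df, df["label"], ForestParams(seed=3)), probe)
        assert np.array_equal(a, b)

    def test_single_class_training_rejected(self):
        df = toy_frame()
        with pytest.raises(ValidationError):
            train_forest(df, np.zeros(len(df), int))

    def test_predict_empty_frame(self):
        df = toy_frame()
        model = train_forest(df, df["label"])
        assert predict(model, df.iloc[:0]).size == 0

    def test_predict_schema_mismatch_rejected(self):
        df = toy_frame()
        model = train_forest(df, df["label"])
        with pytest.raises(ValidationError):
            predict(model, df.drop(columns=["rms"]))


def counting_metrics(y_true, y_pred):
    """Naive per-sample counting oracle for the confusion-derived metrics."""
    conf = np.zeros((3, 3), int)
    for t, p in zip(y_true, y_pred):
        conf[t, p] += 1
    prec, rec, f1 = [], [], []
    for c in range(3):
        tp = conf[c, c]
        fp = conf[:, c].sum() - tp
        fn = conf[c, :].sum() - tp
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        prec.append(p), rec.append(r), f1.append(f)
    return conf, np.array(prec), np.array(rec), np.array(f1)


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 0, 1, 2, 0])
        rep = confusion_and_metrics(y, y)
        assert rep.accuracy == 1.0
        assert np.all(rep.f1 == 1.0)

    def test_direct_one_vs_rest_counts(self):
        # class-1 one-vs-rest: TP=8, FP=2, FN=2
        y_true = [1] * 10 + [0] * 10
        y_pred = [1] * 8 + [0] * 2 + [1] * 2 + [0] * 8
        rep = confusion_and_metrics(y_true, y_pred)
        assert rep.precision[1] == pytest.approx(0.8)
        assert rep.recall[1] == pytest.approx(0.8)
        assert rep.f1[1] == pytest.approx(0.8)

    def test_matches_counting_oracle_on_random_labels(self, rng):
        for _ in range(20):
            y_true = rng.integers(0, 3, 200)
            y_pred = rng.integers(0, 3, 200)
            rep = confusion_and_metrics(y_true, y_pred)
            conf, prec, rec, f1 = counting_metrics(y_true, y_pred)
            assert np.array_equal(rep.confusion, conf)
            assert np.allclose(rep.precision, prec, atol=1e-12)
            assert np.allclose(rep.recall, rec, atol=1e-12)
            assert np.allclose(rep.f1, f1, atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            confusion_and_metrics([0, 1], [0])


class TestCrossValidation:
    def test_separable_toy_is_perfect(self):
        df = toy_frame(n_cycles=20, per_cycle=30)
        mean, folds = cross_validate_accuracy(df, ForestParams(seed=0), k=10)
        assert mean > 0.9
        assert len(folds) == 10

    def test_fold_sizes_balanced_over_cycles(self):
        df = toy_frame(n_cycles=13)
        ids = np.sort(df["cycle_id"].unique())
        rng = np.random.default_rng(0)
        folds = np.array_split(rng.permutation(ids), 10)
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_more_folds_than_cycles_rejected(self):
        df = toy_frame(n_cycles=6)
        with pytest.raises(ConfigurationError):
            cross_validate_accuracy(df, k=10)


class TestModelResults:
    def test_design_a_result_is_fully_populated(self, small_land_corpus):
        res = run_design(small_land_corpus, "A")
        d = res.to_dict()
        assert d["design"] == "A"
        assert np.array(d["confusion"]).shape == (3, 3)
        assert 0 <= d["accuracy"] <= 1
        assert set(d["per_class"]) == {"0", "1", "2"}
        assert res.timing.n_matched > 0
        assert "per-sample accuracy" in res.summary()

    def test_cv_within_holdout_consistency(self, small_land_corpus):
        """Cycle-level CV accuracy agrees with a repeated-holdout estimate."""
        train, _ = split_by_cycles(small_land_corpus, SplitSpec(design="A"))
        cv_mean, _ = cross_validate_accuracy(train, ForestParams(seed=0), k=5)
        holdouts = []
        for seed in (11, 22):
            sub_train, sub_test = split_cycle_pool(train, 0.8, seed)
            m = train_forest(sub_train, sub_train["label"], ForestParams(seed=0))
            holdouts.append(np.mean(predict(m, sub_test) == sub_test["label"]))
        assert abs(cv_mean - np.mean(holdouts)) < 0.03

    def test_end_to_end_predictions_find_every_stride(self, small_land_corpus):
        res = run_design(small_land_corpus, "B")
        total_truth = res.timing.n_matched + res.timing.n_missed
        assert res.timing.n_matched / total_truth > 0.95

    def test_unknown_design_rejected(self, small_land_corpus):
        with pytest.raises(ConfigurationError):
            GaitEventModel(small_land_corpus, design="Z")
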