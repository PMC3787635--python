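"""Metrics, AUC, CV mechanics and the Model/Results objects."""

from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from dbpred.model import (
    BACKENDS,
    ConfusionCounts,
    CVResults,
    DNABindingModel,
    auc,
    decision_scores,
    metrics,
    repeated_cv,
    train_classifier,
)
from dbpred.synthetic import gen_blobs


def exact_metrics(tp, fp, tn, fn):
    """Recomputation of the ratio metrics in exact rational arithmetic.

    MCC involves a square root, so its oracle stays in floats (exact
    integer numerator and denominator, one final sqrt).
    """
    out = {"accuracy": 100 * Fraction(tp + tn, tp + fp + tn + fn)}
    if tp + fn:
        out["sensitivity"] = 100 * Fraction(tp, tp + fn)
    if tn + fp:
        out["specificity"] = 100 * Fraction(tn, tn + fp)
    return out


def test_metrics_frozen_examples():
    perfect = metrics(ConfusionCounts(tp=50, fp=0, tn=50, fn=0))
    assert perfect["accuracy"] == 100.0 and perfect["mcc"] == 1.0
    chance = metrics(ConfusionCounts(tp=25, fp=25, tn=25, fn=25))
    assert chance["accuracy"] == 50.0 and chance["mcc"] == 0.0
    m = metrics(ConfusionCounts(tp=962, fp=299, tn=1033, fn=370))
    ex = exact_metrics(962, 299, 1033, 370)
    assert m["accuracy"] == pytest.approx(float(ex["accuracy"]), abs=1e-12)
    assert m["sensitivity"] == pytest.approx(float(ex["sensitivity"]), abs=1e-12)
    assert m["specificity"] == pytest.approx(float(ex["specificity"]), abs=1e-12)
    mcc_exact = (962 * 1033 - 299 * 370) / np.sqrt(
        float((962 + 299) * (1033 + 370) * (962 + 370) * (1033 + 299))
    )
    assert m["mcc"] == pytest.approx(mcc_exact, abs=1e-12)


def test_metrics_random_tables_match_exact_arithmetic():
    rng = np.random.default_rng(9)
    for _ in range(200):
        tp, fp, tn, fn = rng.integers(0, 500, 4)
        if tp + fp + tn + fn == 0:
            continue
        got = metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
        assert got["accuracy"] == pytest.approx(
            float(100 * Fraction(int(tp + tn), int(tp + fp + tn + fn))), abs=1e-10
        )
        if tp + fn:
            assert got["sensitivity"] == pytest.approx(
                float(100 * Fraction(int(tp), int(tp + fn))), abs=1e-10
            )
        denom = int((tp + fp) * (tn + fn) * (tp + fn) * (tn + fp))
        if denom == 0:
            assert "mcc" not in got
        else:
            exact = (int(tp) * int(tn) - int(fp) * int(fn)) / np.sqrt(float(denom))
            assert got["mcc"] == pytest.approx(exact, abs=1e-10)


def test_undefined_metrics_absent_not_zero():
    m = metrics(ConfusionCounts(tp=5, fp=0, tn=0, fn=3))  # no negatives seen
    assert "sensitivity" in m and "specificity" not in m and "mcc" not in m
    with pytest.raises(ValueError, match="zero"):
        ConfusionCounts(0, 0, 0, 0)


def test_auc_examples_and_mann_whitney_identity():
    assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
    scores = [0.9, 0.8, 0.2, 0.1]
    assert auc(scores, [1, 1, 0, 0]) + auc([-s for s in scores], [1, 1, 0, 0]) == 1.0
    rng = np.random.default_rng(13)
    for _ in range(20):
        n_pos, n_neg = rng.integers(5, 60, 2)
        labels = np.r_[np.ones(n_pos, bool), np.zeros(n_neg, bool)]
        scores = np.round(rng.normal(labels * 0.5, 1.0), 1)  # ties likely
        u = mannwhitneyu(scores[labels], scores[~labels]).statistic
        assert auc(scores, labels) == pytest.approx(u / (n_pos * n_neg), abs=1e-12)


def test_auc_single_class_rejected():
    with pytest.raises(ValueError):
        auc([0.1, 0.2], [1, 1])


def test_auc_chance_level_on_independent_labels():
    rng = np.random.default_rng(21)
    labels = rng.random(10000) < 0.5
    scores = rng.normal(size=10000)
    assert auc(scores, labels) == pytest.approx(0.5, abs=0.02)


def test_train_classifier_contract():
    X, y = gen_blobs(n_per_class=40, dim=2, separation=8, seed=0)
    model = train_classifier(X, y)
    assert (model.predict(X) == y).all()  # separable: 100% training accuracy
    assert decision_scores(model, X).shape == (80,)
    # determinism: duplicated data, same seed -> identical decision function
    m2 = train_classifier(np.vstack([X, X]), np.r_[y, y])
    grid = np.random.default_rng(0).normal(size=(50, 2))
    m3 = train_classifier(np.vstack([X, X]), np.r_[y, y])
    assert np.allclose(decision_scores(m2, grid), decision_scores(m3, grid))
    with pytest.raises(ValueError, match="classes"):
        train_classifier(X, np.ones(80, bool))


@pytest.mark.parametrize("backend", BACKENDS)
def test_all_backends_fit_and_score(backend):
    X, y = gen_blobs(n_per_class=30, dim=3, separation=6, seed=1)
    model = train_classifier(X, y, backend=backend, seed=5)
    assert decision_scores(model, X).shape == (60,)
    assert (model.predict(X) == y).mean() > 0.9


def test_repeated_cv_partition_and_reproducibility():
    X, y = gen_blobs(n_per_class=30, dim=4, separation=2, seed=2)
    res = repeated_cv(X, y, k=5, repetitions=2, seed=7)
    assert isinstance(res, CVResults)
    assert len(res.folds) == 10
    # each repetition's test folds partition the dataset
    for rep in range(2):
        sizes = res.folds.query("repetition == @rep")[["tp", "fp", "tn", "fn"]].sum(axis=1)
        assert sizes.sum() == 60
    res2 = repeated_cv(X, y, k=5, repetitions=2, seed=7)
    assert res.folds.equals(res2.folds)  # bit-identical under fixed seed
    assert res.fingerprint == res2.fingerprint
    res3 = repeated_cv(X, y, k=5, repetitions=2, seed=8)
    assert not res.folds.equals(res3.folds)


def test_averaged_metrics_are_fold_means():
    X, y = gen_blobs(n_per_class=25, dim=3, separation=3, seed=3)
    res = repeated_cv(X, y, k=5, repetitions=2, seed=0)
    for name in ("accuracy", "sensitivity", "specificity", "mcc", "auc"):
        assert getattr(res, name) == pytest.approx(
            np.nanmean(res.folds[name].to_numpy(float)), abs=1e-12
        )


def test_repeated_cv_refuses_unstratifiable_input():
    X = np.random.default_rng(0).normal(size=(10, 2))
    y = np.r_[np.ones(2, bool), np.zeros(8, bool)]
    with pytest.raises(ValueError, match="stratify"):
        repeated_cv(X, y, k=5)


def test_accuracy_nondecreasing_in_separation():
    accs = []
    for sep in (0.5, 2.0, 6.0):
        X, y = gen_blobs(n_per_class=60, dim=5, separation=sep, seed=4)
        accs.append(repeated_cv(X, y, k=5, repetitions=1, seed=0).accuracy)
    assert accs[0] <= accs[1] <= accs[2]


def test_model_results_objects():
    X, y = gen_blobs(n_per_class=30, dim=4, separation=6, seed=5)
    import pandas as pd

    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(4)])
    df["label"] = ["binding" if t else "nonbinding" for t in y]
    model = DNABindingModel.from_dataframe(df)
    res = model.fit(k=5, repetitions=1, seed=0)
    assert res.accuracy > 95
    text = res.summary()
    assert "svm-smo" in text and "accuracy" in text and res.fingerprint in text
    handle = model.fit_full(seed=0)
    assert (handle.predict(X) == y).all()
    with pytest.raises(ValueError, match="backend"):
        DNABindingModel(X, y, backend="weka")
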