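"""Classifier training and repeated cross-validated evaluation.

The modelling surface follows the statsmodels convention: a
:class:`DNABindingModel` is built from a feature matrix and labels (or a
DataFrame), and its :meth:`~DNABindingModel.fit` runs repeated stratified
k-fold cross-validation, returning a :class:`CVResults` object that
carries per-fold confusion counts and decision scores, the averaged
metrics, a config fingerprint and a ``summary()`` table.

Metrics are the four standard confusion-matrix statistics

.. math::

   Acc = \\frac{TP+TN}{TP+FP+TN+FN},\\quad
   Sn = \\frac{TP}{TP+FN},\\quad
   Sp = \\frac{TN}{TN+FP},\\quad
   MCC = \\frac{TP \\cdot TN - FP \\cdot FN}
        {\\sqrt{(TP+FP)(TN+FN)(TP+FN)(TN+FP)}}

plus the area under the ROC curve computed from continuous decision
scores. A metric whose denominator vanishes is reported as absent (NaN in
tables), never as 0.

The default backend is an SMO-family support vector machine (libsvm via
scikit-learn) with a linear kernel and unit cost; simple logistic
regression, random forest, naive Bayes and a CART decision tree are
available behind the same contract. Features are standardized with
train-split statistics before margin-based fits (toggleable) because the
EI block's scale — sums over residue counts — otherwise dominates.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from dbpred.seqio import Label

BACKENDS = (
    "svm-smo",
    "simple-logistic",
    "random-forest",
    "naive-bayes",
    "decision-tree",
)

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "mcc", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN counts for one evaluation."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=bool)
        y_pred = np.asarray(y_pred, dtype=bool)
        return cls(
            tp=int(np.count_nonzero(y_true & y_pred)),
            fp=int(np.count_nonzero(~y_true & y_pred)),
            tn=int(np.count_nonzero(~y_true & ~y_pred)),
            fn=int(np.count_nonzero(y_true & ~y_pred)),
        )


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and MCC from confusion counts.

    Accuracy, sensitivity and specificity are returned as percentages; MCC
    on its natural [-1, 1] scale. Metrics with a zero denominator are
    omitted from the result rather than reported as 0.
    """
    out: dict[str, float] = {
        "accuracy": 100.0 * (counts.tp + counts.tn) / counts.total
    }
    if counts.tp + counts.fn > 0:
        out["sensitivity"] = 100.0 * counts.tp / (counts.tp + counts.fn)
    if counts.tn + counts.fp > 0:
        out["specificity"] = 100.0 * counts.tn / (counts.tn + counts.fp)
    denom = (
        (counts.tp + counts.fp)
        * (counts.tn + counts.fn)
        * (counts.tp + counts.fn)
        * (counts.tn + counts.fp)
    )
    if denom > 0:
        out["mcc"] = (counts.tp * counts.tn - counts.fp * counts.fn) / np.sqrt(
            float(denom)
        )
    return out


def auc(scores: Sequence[float], labels: Sequence[bool | int]) -> float:
    """Area under the ROC curve from continuous scores (midrank for ties)."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("AUC needs at least one positive and one negative")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _make_backend(backend: str, params: dict | None, seed: int | None):
    params = dict(params or {})
    if backend == "svm-smo":
        params.setdefault("kernel", "linear")
        params.setdefault("C", 1.0)
        return SVC(random_state=seed, **params)
    if backend == "simple-logistic":
        params.setdefault("max_iter", 5000)
        return LogisticRegression(random_state=seed, **params)
    if backend == "random-forest":
        return RandomForestClassifier(random_state=seed, **params)
    if backend == "naive-bayes":
        return GaussianNB(**params)
    if backend == "decision-tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    raise ValueError(f"unknown backend {backend!r}; known: {BACKENDS}")


def _as_binary(labels: Sequence) -> np.ndarray:
    """Map labels to a boolean array with the binding class as positive."""
    out = []
    for lab in labels:
        if isinstance(lab, Label):
            out.append(lab is Label.BINDING)
        elif isinstance(lab, str):
            out.append(lab.lower() in ("binding", "1", "true", "pos", "positive"))
        else:
            out.append(bool(lab))
    return np.asarray(out, dtype=bool)


def train_classifier(
    matrix,
    labels: Sequence,
    backend: str = "svm-smo",
    params: dict | None = None,
    seed: int | None = 0,
    standardize: bool = True,
):
    """Fit a classifier; the handle exposes ``predict`` and decision scores.

    The fitted object is an sklearn pipeline (optional standardizer +
    backend); :func:`decision_scores` extracts a continuous score per
    instance for ROC analysis.
    """
    X = np.asarray(matrix, dtype=float)
    y = _as_binary(labels)
    if y.all() or not y.any():
        raise ValueError("training requires both classes to be present")
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    steps = []
    if standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("clf", _make_backend(backend, params, seed)))
    pipe = Pipeline(steps)
    pipe.fit(X, y)
    return pipe


def decision_scores(model, X) -> np.ndarray:
    """Continuous decision scores (margin, else positive-class probability)."""
    clf = model[-1] if isinstance(model, Pipeline) else model
    if hasattr(clf, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    proba = model.predict_proba(X)
    return np.asarray(proba[:, list(model.classes_).index(True)], dtype=float)


@dataclass(frozen=True)
class CVResults:
    """Results of repeated stratified k-fold cross-validation.

    ``folds`` is a tidy DataFrame with one row per (repetition, fold)
    carrying the confusion counts and all per-fold metrics; ``scores``
    keeps the decision scores and true labels of every fold's test set so
    ROC curves can be re-plotted. Averaged metrics are the plain mean of
    the per-fold values (NaN-skipping where a fold's metric was undefined).
    """

    folds: pd.DataFrame
    scores: list[tuple[np.ndarray, np.ndarray]] = field(repr=False)
    k: int
    repetitions: int
    seed: int
    backend: str
    config: dict = field(repr=False)

    @property
    def fingerprint(self) -> str:
        """Hex digest identifying the evaluation configuration."""
        blob = json.dumps(self.config, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def _mean(self, name: str) -> float:
        vals = self.folds[name].to_numpy(dtype=float)
        return float(np.nanmean(vals)) if not np.isnan(vals).all() else float("nan")

    @property
    def accuracy(self) -> float:
        return self._mean("accuracy")

    @property
    def sensitivity(self) -> float:
        return self._mean("sensitivity")

    @property
    def specificity(self) -> float:
        return self._mean("specificity")

    @property
    def mcc(self) -> float:
        return self._mean("mcc")

    @property
    def auc(self) -> float:
        return self._mean("auc")

    def as_dict(self) -> dict[str, float]:
        return {name: self._mean(name) for name in METRIC_NAMES}

    def summary(self) -> str:
        """Human-readable evaluation summary table."""
        lines = [
            "Repeated stratified cross-validation results",
            "=" * 44,
            f"backend:       {self.backend}",
            f"folds:         {self.k} x {self.repetitions} repetitions",
            f"seed:          {self.seed}",
            f"fingerprint:   {self.fingerprint}",
            "-" * 44,
            f"{'metric':<14}{'mean':>10}{'std':>10}",
        ]
        for name in METRIC_NAMES:
            vals = self.folds[name].to_numpy(dtype=float)
            mean = np.nanmean(vals)
            std = np.nanstd(vals)
            unit = "%" if name in ("accuracy", "sensitivity", "specificity") else " "
            lines.append(f"{name:<14}{mean:>9.2f}{unit}{std:>10.3f}")
        lines.append("=" * 44)
        return "\n".join(lines)


def repeated_cv(
    matrix,
    labels: Sequence,
    k: int = 5,
    repetitions: int = 5,
    seed: int = 0,
    backend: str = "svm-smo",
    params: dict | None = None,
    standardize: bool = True,
) -> CVResults:
    """Repeated stratified k-fold cross-validation, reproducible from seed.

    Each repetition draws a fresh stratified partition into ``k`` equal
    parts; each part serves once as the test set while the rest train the
    classifier. Standardization statistics come from the training split
    only. Per-fold metrics are averaged over all ``k * repetitions`` folds.
    """
    X = np.asarray(matrix, dtype=float)
    y = _as_binary(labels)
    n_min = min(int(y.sum()), int((~y).sum()))
    if n_min < k:
        raise ValueError(
            f"smallest class has {n_min} members; cannot stratify into {k} folds"
        )
    splitter = RepeatedStratifiedKFold(
        n_splits=k, n_repeats=repetitions, random_state=seed
    )
    rows = []
    scores_store: list[tuple[np.ndarray, np.ndarray]] = []
    for run, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
        model = train_classifier(
            X[train_idx], y[train_idx], backend=backend, params=params,
            seed=seed, standardize=standardize,
        )
        y_pred = model.predict(X[test_idx])
        y_test = y[test_idx]
        counts = ConfusionCounts.from_predictions(y_test, y_pred)
        fold_metrics = metrics(counts)
        s = decision_scores(model, X[test_idx])
        scores_store.append((s, y_test))
        row = {
            "repetition": run // k,
            "fold": run % k,
            "tp": counts.tp,
            "fp": counts.fp,
            "tn": counts.tn,
            "fn": counts.fn,
        }
        for name in ("accuracy", "sensitivity", "specificity", "mcc"):
            row[name] = fold_metrics.get(name, np.nan)
        row["auc"] = (
            auc(s, y_test) if 0 < y_test.sum() < y_test.size else np.nan
        )
        rows.append(row)
    config = {
        "backend": backend,
        "params": params or {},
        "k": k,
        "repetitions": repetitions,
        "seed": seed,
        "standardize": standardize,
        "n": int(X.shape[0]),
        "p": int(X.shape[1]),
    }
    return CVResults(
        folds=pd.DataFrame(rows),
        scores=scores_store,
        k=k,
        repetitions=repetitions,
        seed=seed,
        backend=backend,
        config=config,
    )


class DNABindingModel:
    """A binary DNA-binding-protein classifier over a feature matrix.

    Parameters
    ----------
    matrix : array-like or DataFrame, shape (n_proteins, n_features)
        Feature matrix (any subset of the hybrid blocks).
    labels : sequence
        Class labels; :class:`~dbpred.seqio.Label`, strings or booleans,
        binding = positive.
    backend : str
        One of :data:`BACKENDS`; default the linear-kernel SVM.
    params : dict, optional
        Backend hyperparameters (e.g. ``{"C": 1.0}``).
    standardize : bool
        Standardize features with train-split statistics before fitting.
    """

    def __init__(
        self,
        matrix,
        labels: Sequence,
        backend: str = "svm-smo",
        params: dict | None = None,
        standardize: bool = True,
    ):
        if backend not in BACKENDS:
            raise ValueError(f"unknown backend {backend!r}; known: {BACKENDS}")
        self.matrix = (
            matrix if isinstance(matrix, pd.DataFrame) else pd.DataFrame(np.asarray(matrix))
        )
        self.labels = list(labels)
        if len(self.labels) != len(self.matrix):
            raise ValueError("labels and matrix row counts differ")
        self.backend = backend
        self.params = dict(params or {})
        self.standardize = standardize

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_col: str = "label", **kwargs
    ) -> "DNABindingModel":
        """Build a model from a DataFrame with a label column."""
        if label_col not in df.columns:
            raise ValueError(f"no column {label_col!r} in DataFrame")
        labels = df[label_col].tolist()
        return cls(df.drop(columns=[label_col]), labels, **kwargs)

    def fit(self, k: int = 5, repetitions: int = 5, seed: int = 0) -> CVResults:
        """Evaluate by repeated stratified k-fold CV; returns :class:`CVResults`."""
        return repeated_cv(
            self.matrix.to_numpy(dtype=float),
            self.labels,
            k=k,
            repetitions=repetitions,
            seed=seed,
            backend=self.backend,
            params=self.params,
            standardize=self.standardize,
        )

    def fit_full(self, seed: int = 0):
        """Fit the backend on all rows; returns the fitted pipeline handle."""
        return train_classifier(
            self.matrix.to_numpy(dtype=float),
            self.labels,
            backend=self.backend,
            params=self.params,
            seed=seed,
            standardize=self.standardize,
        )


def ablation(
    proteins,
    tracks,
    pssms,
    subsets: Sequence[str] | None = None,
    backends: Sequence[str] = ("svm-smo",),
    k: int = 5,
    repetitions: int = 5,
    seed: int = 0,
    config=None,
) -> pd.DataFrame:
    """Evaluate every (feature subset, backend) cell of the ablation grid.

    Returns a tidy DataFrame with one row per cell and the averaged CV
    metrics as columns, mirroring the standard feature-ablation table.
    """
    from dbpred.features import SUBSETS, batch_features

    subsets = list(subsets) if subsets is not None else list(SUBSETS)
    rows = []
    for subset in subsets:
        matrix, labels = batch_features(
            proteins, tracks=tracks, pssms=pssms, subset=subset, config=config
        )
        for backend in backends:
            res = DNABindingModel(matrix, labels, backend=backend).fit(
                k=k, repetitions=repetitions, seed=seed
            )
            row = {"subset": subset, "backend": backend, "n_features": matrix.shape[1]}
            row.update(res.as_dict())
            rows.append(row)
    return pd.DataFrame(rows)
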