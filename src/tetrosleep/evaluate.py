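"""Cubic-SVM cross-validated evaluation and summary metrics.

The reference classifier is a third-degree polynomial ("cubic") SVM with
box constraint C = 1, kernel scale 1, offset 1 and one-vs-one multiclass
handling, evaluated under seeded stratified 10-fold cross-validation.
Test predictions from all folds are pooled into a single confusion matrix
from which six summary metrics are derived with macro (unweighted
per-class) averaging: accuracy, F1-score, average precision, geometric
mean of recalls, sensitivity (macro recall) and specificity.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import BaggingClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import InvalidInputError

__all__ = [
    "EvalReport",
    "cubic_svm",
    "cross_validate",
    "metrics_from_confusion",
    "compare_classifiers",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = (
    "accuracy",
    "f1_score",
    "average_precision",
    "geometric_mean",
    "sensitivity",
    "specificity",
)


def cubic_svm(kernel: str = "poly") -> SVC:
    """The reference cubic SVM (C=1, (1 + x.y)^3 kernel, one-vs-one)."""
    if kernel == "precomputed":
        return SVC(kernel="precomputed", C=1.0)
    return SVC(kernel="poly", degree=3, gamma=1.0, coef0=1.0, C=1.0)


@dataclass
class EvalReport:
    """Pooled cross-validation outcome.

    confusion[i, j] counts epochs of true class ``classes[i]`` predicted
    as ``classes[j]``; fold accuracies and metrics are percentages.
    """

    classes: list
    confusion: np.ndarray
    fold_accuracies: np.ndarray
    metrics: dict = field(default_factory=dict)

    def validate(self) -> None:
        C = self.confusion
        if (C < 0).any():
            raise AssertionError("negative confusion counts")
        acc = 100.0 * np.trace(C) / C.sum()
        if abs(acc - self.metrics["accuracy"]) > 1e-9:
            raise AssertionError("accuracy does not match the confusion trace")

    def to_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
            "fold_accuracies": self.fold_accuracies.tolist(),
            "metrics": {k: float(v) for k, v in self.metrics.items()},
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def save_fold_csv(self, path) -> None:
        lines = ["fold,accuracy"] + [
            f"{i + 1},{float(a)!r}" for i, a in enumerate(self.fold_accuracies)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    def render_confusion(self) -> str:
        names = [str(c) for c in self.classes]
        width = max(5, max(len(n) for n in names) + 1)
        head = " " * width + "".join(f"{n:>{width}}" for n in names)
        rows = [
            f"{n:>{width}}" + "".join(f"{v:>{width}d}" for v in row)
            for n, row in zip(names, self.confusion)
        ]
        return "\n".join([head] + rows)


def metrics_from_confusion(confusion) -> dict:
    """Six macro-averaged summary metrics (percent) of a confusion matrix."""
    C = np.asarray(confusion, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1] or (C < 0).any():
        raise InvalidInputError("confusion must be a square nonnegative matrix")
    total = C.sum()
    if total == 0:
        raise InvalidInputError("empty confusion matrix")
    tp = np.diag(C)
    support = C.sum(axis=1)
    predicted = C.sum(axis=0)

    recall = np.divide(tp, support, out=np.zeros_like(tp), where=support > 0)
    if (predicted == 0).any():
        logger.warning(
            "classes %s were never predicted; their precision is counted as 0",
            np.flatnonzero(predicted == 0).tolist(),
        )
    precision = np.divide(tp, predicted, out=np.zeros_like(tp), where=predicted > 0)
    fn = support - tp
    fp = predicted - tp
    tn = total - tp - fn - fp
    specificity = np.divide(tn, tn + fp, out=np.zeros_like(tn), where=(tn + fp) > 0)
    pr = precision + recall
    f1 = np.divide(2 * precision * recall, pr, out=np.zeros_like(pr), where=pr > 0)

    return {
        "accuracy": 100.0 * tp.sum() / total,
        "f1_score": 100.0 * f1.mean(),
        "average_precision": 100.0 * precision.mean(),
        "geometric_mean": 100.0 * float(np.prod(recall) ** (1.0 / len(recall))),
        "sensitivity": 100.0 * recall.mean(),
        "specificity": 100.0 * specificity.mean(),
    }


def _check_cv_inputs(X, y, folds):
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise InvalidInputError("features must be 2-D with one label per row")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        small = classes[counts.argmin()]
        raise InvalidInputError(
            f"class {small!r} has {counts.min()} members, fewer than {folds} folds"
        )
    return classes


def cross_validate(features, labels, folds: int = 10, seed: int = 0, estimator=None) -> EvalReport:
    """Seeded stratified k-fold evaluation of the cubic SVM.

    Returns an :class:`EvalReport` with the fold-pooled confusion matrix,
    per-fold accuracies and the six summary metrics.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = _check_cv_inputs(X, y, folds)
    index = {c: i for i, c in enumerate(classes)}
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    fold_acc = []
    for train, test in skf.split(X, y):
        clf = cubic_svm() if estimator is None else estimator()
        clf.fit(X[train], y[train])
        pred = clf.predict(X[test])
        fold_acc.append(100.0 * float((pred == y[test]).mean()))
        for t, p in zip(y[test], pred):
            confusion[index[t], index[p]] += 1
    report = EvalReport(
        classes=list(classes),
        confusion=confusion,
        fold_accuracies=np.asarray(fold_acc),
        metrics=metrics_from_confusion(confusion),
    )
    report.validate()
    return report


def _classifier_zoo(seed: int) -> dict:
    return {
        "DT": lambda: DecisionTreeClassifier(random_state=seed),
        "LD": lambda: LinearDiscriminantAnalysis(),
        "NB": lambda: GaussianNB(),
        "LSVM": lambda: SVC(kernel="linear", C=1.0),
        "QSVM": lambda: SVC(kernel="poly", degree=2, gamma=1.0, coef0=1.0, C=1.0),
        "CSVM": lambda: cubic_svm(),
        "kNN": lambda: KNeighborsClassifier(n_neighbors=10),
        "BT": lambda: BaggingClassifier(
            DecisionTreeClassifier(random_state=seed), n_estimators=30, random_state=seed
        ),
    }


def compare_classifiers(features, labels, folds: int = 10, seed: int = 0) -> pd.DataFrame:
    """Accuracy of eight shallow classifiers under identical folds.

    Returns a DataFrame with one row per classifier (DT, LD, NB, LSVM,
    QSVM, CSVM, kNN, BT) and an ``accuracy`` column in percent.
    """
    rows = [
        {"classifier": name, "accuracy": cross_validate(
            features, labels, folds=folds, seed=seed, estimator=make
        ).metrics["accuracy"]}
        for name, make in _classifier_zoo(seed).items()
    ]
    return pd.DataFrame(rows)
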