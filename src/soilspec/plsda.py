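"""Discriminant layer on top of PLS2: indicator coding, argmax assignment,
confusion matrices, accuracy metrics, LOO cross-validation and
accuracy-vs-components curves.

PLSDA here means: regress a 0/1 class-indicator matrix (one column per
class) on the centered spectra with PLS2, then assign each sample to the
class with the largest predicted response.  Exact ties go to the earliest
class in the declared class order — deterministic and documented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .dataset import SpectraSet
from .pls import PLS2Regression


# ---------------------------------------------------------------------------
# indicator coding and class assignment
# ---------------------------------------------------------------------------
def encode_indicator(labels: Sequence[str], class_order: Sequence[str]) -> np.ndarray:
    """0/1 membership matrix, one column per class in ``class_order``."""
    class_order = list(class_order)
    pos = {c: j for j, c in enumerate(class_order)}
    Y = np.zeros((len(labels), len(class_order)))
    for i, lab in enumerate(labels):
        if lab not in pos:
            raise ValueError(f"label {lab!r} not in class order {class_order}")
        Y[i, pos[lab]] = 1.0
    return Y


def decode_indicator(Y: np.ndarray, class_order: Sequence[str]) -> list[str]:
    class_order = list(class_order)
    return [class_order[j] for j in np.argmax(Y, axis=1)]


def assign_class(predicted: np.ndarray, class_order: Sequence[str]) -> list[str]:
    """Largest-predicted-value rule; ties -> earliest class in order."""
    P = np.atleast_2d(np.asarray(predicted, dtype=float))
    bad_rows = np.flatnonzero(~np.isfinite(P).all(axis=1))
    if bad_rows.size:
        raise ValueError(f"non-finite prediction in row {int(bad_rows[0])}")
    class_order = list(class_order)
    if len(class_order) < 2:
        raise ValueError("need at least 2 classes")
    # np.argmax returns the first maximum -> earliest class wins ties
    return [class_order[j] for j in np.argmax(P, axis=1)]


# ---------------------------------------------------------------------------
# confusion matrices and accuracies
# ---------------------------------------------------------------------------
@dataclass
class ConfusionMatrix:
    """True-by-predicted counts in a fixed class order."""

    counts: np.ndarray
    class_order: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.class_order = tuple(self.class_order)
        K = len(self.class_order)
        if self.counts.shape != (K, K):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match {K} classes"
            )
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_order: Sequence[str],
) -> ConfusionMatrix:
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"{len(true_labels)} true vs {len(predicted_labels)} predicted labels"
        )
    class_order = tuple(class_order)
    pos = {c: j for j, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        counts[pos[t], pos[p]] += 1
    return ConfusionMatrix(counts, class_order)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """100 * trace / total, in percent."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * np.trace(cm.counts) / cm.total


def per_class_accuracy(cm: ConfusionMatrix) -> np.ndarray:
    """100 * diagonal / row sum per class; empty classes are NaN, not 0."""
    rows = cm.counts.sum(axis=1).astype(float)
    diag = np.diag(cm.counts).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        acc = 100.0 * diag / rows
    acc[rows == 0] = np.nan
    return acc


@dataclass
class AccuracyReport:
    """Per-class and overall accuracy of one confusion matrix."""

    confusion: ConfusionMatrix
    per_class: np.ndarray
    overall: float
    n_components: int | None = None
    feature_subset: tuple[int, ...] | None = None

    @classmethod
    def from_confusion(
        cls,
        cm: ConfusionMatrix,
        n_components: int | None = None,
        feature_subset: Sequence[int] | None = None,
    ) -> "AccuracyReport":
        return cls(
            cm,
            per_class_accuracy(cm),
            overall_accuracy(cm),
            n_components,
            None if feature_subset is None else tuple(feature_subset),
        )


# ---------------------------------------------------------------------------
# the classifier
# ---------------------------------------------------------------------------
class PLSDAClassifier(ClassifierMixin, BaseEstimator):
    """PLS2 regression onto a class-indicator matrix + argmax assignment.

    Parameters
    ----------
    n_components : number of latent variables (the study's final model
        uses 26).
    class_order : explicit ordered class list; defaults to the sorted
        unique labels seen in ``fit`` (pass the declared order to match a
        :class:`~soilspec.dataset.SpectraSet`).
    """

    def __init__(
        self,
        n_components: int = 26,
        class_order: Sequence[str] | None = None,
    ):
        self.n_components = n_components
        self.class_order = class_order

    def fit(self, X, y) -> "PLSDAClassifier":
        y = list(map(str, y))
        if self.class_order is None:
            classes = tuple(sorted(set(y)))
        else:
            classes = tuple(self.class_order)
        self.classes_ = np.asarray(classes, dtype=object)
        Y = encode_indicator(y, classes)
        self.pls_ = PLS2Regression(n_components=self.n_components).fit(X, Y)
        return self

    def decision_function(self, X, n_components: int | None = None) -> np.ndarray:
        """Continuous predicted indicator values (m x K)."""
        return self.pls_.predict(X, n_components=n_components)

    def predict(self, X, n_components: int | None = None) -> np.ndarray:
        scores = self.decision_function(X, n_components=n_components)
        return np.asarray(assign_class(scores, list(self.classes_)), dtype=object)

    def score(self, X, y) -> float:
        """Fraction correctly classified (sklearn convention, 0..1)."""
        return float(np.mean(self.predict(X) == np.asarray(y, dtype=object)))


# ---------------------------------------------------------------------------
# dataset-level conveniences
# ---------------------------------------------------------------------------
def _maybe_subset(spectra: SpectraSet, feature_subset: Sequence[int] | None) -> SpectraSet:
    return spectra if feature_subset is None else spectra.select_features(feature_subset)


def fit_plsda(
    train: SpectraSet,
    n_components: int,
    feature_subset: Sequence[int] | None = None,
) -> PLSDAClassifier:
    sub = _maybe_subset(train, feature_subset)
    return PLSDAClassifier(n_components=n_components, class_order=sub.class_order).fit(
        sub.absorbance, sub.labels
    )


def train_confusion(
    train: SpectraSet,
    n_components: int,
    feature_subset: Sequence[int] | None = None,
) -> ConfusionMatrix:
    """Calibration (resubstitution) confusion matrix on the training set."""
    sub = _maybe_subset(train, feature_subset)
    clf = fit_plsda(sub, n_components)
    pred = clf.predict(sub.absorbance)
    return confusion(sub.labels, list(pred), sub.class_order)


def test_confusion(
    train: SpectraSet,
    test: SpectraSet,
    n_components: int,
    feature_subset: Sequence[int] | None = None,
) -> ConfusionMatrix:
    """External-validation confusion matrix on a held-out test set."""
    tr = _maybe_subset(train, feature_subset)
    te = _maybe_subset(test, feature_subset)
    clf = fit_plsda(tr, n_components)
    pred = clf.predict(te.absorbance)
    return confusion(te.labels, list(pred), te.class_order)


def loo_cv(
    train: SpectraSet,
    n_components: int,
    feature_subset: Sequence[int] | None = None,
) -> ConfusionMatrix:
    """Leave-one-out cross-validation confusion matrix.

    Each fold refits the PLSDA from scratch on the remaining n-1 samples
    (means re-computed inside the fold, so no information leaks from the
    held-out spectrum) and classifies the held-out sample.
    """
    sub = _maybe_subset(train, feature_subset)
    n = sub.n_samples
    if n_components > n - 2:
        raise ValueError(
            f"n_components={n_components} infeasible for LOO with n={n} "
            f"(needs n_components <= n-2)"
        )
    preds: list[str] = []
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        clf = PLSDAClassifier(
            n_components=n_components, class_order=sub.class_order
        ).fit(sub.absorbance[mask], [l for l, m in zip(sub.labels, mask) if m])
        preds.append(str(clf.predict(sub.absorbance[i : i + 1])[0]))
        mask[i] = True
    return confusion(sub.labels, preds, sub.class_order)


def accuracy_curve(
    train: SpectraSet,
    test: SpectraSet | None = None,
    max_components: int = 30,
    feature_subset: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Calibration, LOO and external accuracy (%) for 1..max_components.

    One model per LOO fold is fitted at ``max_components`` and truncated to
    every smaller component count, so the cost is one fit per fold rather
    than one per fold per component.
    """
    tr = _maybe_subset(train, feature_subset)
    te = _maybe_subset(test, feature_subset) if test is not None else None
    n, K = tr.n_samples, len(tr.class_order)
    A = int(max_components)
    if A > min(n - 2, tr.n_features):
        raise ValueError(
            f"max_components={A} infeasible (n={n}, p={tr.n_features})"
        )
    labels = tr.label_array()

    full = fit_plsda(tr, A)
    cal_all = full.pls_.predict_all_components(tr.absorbance)  # (A, n, K)
    ext_all = (
        full.pls_.predict_all_components(te.absorbance) if te is not None else None
    )

    loo_pred = np.empty((A, n), dtype=object)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        clf = PLSDAClassifier(n_components=A, class_order=tr.class_order).fit(
            tr.absorbance[mask], labels[mask]
        )
        scores = clf.pls_.predict_all_components(tr.absorbance[i : i + 1])  # (A,1,K)
        for a in range(A):
            loo_pred[a, i] = assign_class(scores[a], list(tr.class_order))[0]
        mask[i] = True

    rows = []
    for a in range(1, A + 1):
        cal = assign_class(cal_all[a - 1], list(tr.class_order))
        row = {
            "n_components": a,
            "calibration": overall_accuracy(confusion(tr.labels, cal, tr.class_order)),
            "loo": overall_accuracy(
                confusion(tr.labels, list(loo_pred[a - 1]), tr.class_order)
            ),
        }
        if te is not None:
            ext = assign_class(ext_all[a - 1], list(te.class_order))
            row["external"] = overall_accuracy(
                confusion(te.labels, ext, te.class_order)
            )
        rows.append(row)
    return pd.DataFrame(rows)
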