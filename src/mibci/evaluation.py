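"""Classifier training and cross-validated evaluation.

Three classifiers are supported, all through scikit-learn: a linear-kernel
SVM (C = 1), LDA (least-squares solver with automatic shrinkage, which stays
well-defined when the feature count exceeds the trial count), and KNN with
Euclidean distance (k = 5, odd so binary votes never tie).

Evaluation is stratified k-fold cross-validation (default 10 folds) from a
seeded shuffle. When a feature selector is supplied it is refit inside each
training fold only, so reported accuracies carry no selection leakage. Each
fold contributes a confusion-count quadruple (TP, FN, TN, FP) from which
accuracy, sensitivity, specificity, precision and F1 are computed, plus a
score-based ROC AUC; the report aggregates fold means and standard
deviations. The positive class is the lexicographically larger label unless
overridden, which fixes the orientation of sensitivity vs. specificity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .exceptions import (
    DegenerateFoldError,
    ParameterError,
    StratificationError,
    UndefinedMetricError,
)

__all__ = [
    "ConfusionCounts",
    "FoldResult",
    "EvaluationReport",
    "make_classifier",
    "decision_scores",
    "train_predict",
    "metrics",
    "roc_auc",
    "crossvalidate",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts for one evaluated set of trials."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @classmethod
    def from_labels(cls, y_true, y_pred, positive) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos_t = y_true == positive
        pos_p = y_pred == positive
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
        )

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fn + other.fn,
                               self.tn + other.tn, self.fp + other.fp)


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, precision and F1 from counts.

    A zero denominator yields NaN (an explicit undefined marker), never a
    silent 0.
    """
    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    acc = ratio(counts.tp + counts.tn, counts.n)
    sens = ratio(counts.tp, counts.tp + counts.fn)
    spec = ratio(counts.tn, counts.tn + counts.fp)
    prec = ratio(counts.tp, counts.tp + counts.fp)
    if math.isnan(prec) or math.isnan(sens) or prec + sens == 0:
        f1 = math.nan
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec,
            "precision": prec, "f1": f1}


def roc_auc(scores, y, positive=None) -> float:
    """Trapezoidal area under the ROC curve from continuous scores.

    Equivalent to the Mann–Whitney pair-counting statistic with tied scores
    counted half.
    """
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ParameterError("scores must be finite")
    classes = np.unique(y)
    if classes.size != 2:
        raise UndefinedMetricError("AUC needs both classes present")
    if positive is None:
        positive = classes[-1]
    return float(roc_auc_score((y == positive).astype(int), scores))


def make_classifier(spec: str, knn_k: int = 5, svm_c: float = 1.0):
    """Instantiate one of the three supported classifiers.

    svm-linear: SVC with linear kernel (margin scores via decision_function).
    lda: least-squares LDA with automatic shrinkage (robust to singular
    within-class covariance when features outnumber trials).
    knn: Euclidean k-nearest-neighbors with odd k.
    """
    if spec == "svm-linear":
        return SVC(kernel="linear", C=svm_c)
    if spec == "lda":
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    if spec == "knn":
        if knn_k % 2 == 0:
            raise ParameterError("knn_k must be odd to avoid vote ties")
        return KNeighborsClassifier(n_neighbors=knn_k, metric="euclidean")
    raise ParameterError(f"unknown classifier spec {spec!r}")


def decision_scores(estimator, X, positive) -> np.ndarray:
    """Continuous score per row, oriented toward the positive class.

    SVM: signed margin; probabilistic classifiers: positive-class minus
    negative-class posterior (for KNN this is the signed vote fraction).
    """
    classes = list(estimator.classes_)
    pos_idx = classes.index(positive)
    if hasattr(estimator, "decision_function"):
        s = np.asarray(estimator.decision_function(X), dtype=float)
        # sklearn orients decision_function toward classes_[1]
        return s if pos_idx == 1 else -s
    proba = np.asarray(estimator.predict_proba(X), dtype=float)
    return proba[:, pos_idx] - proba[:, 1 - pos_idx]


def train_predict(train_X, train_y, test_X, spec: str = "svm-linear",
                  positive=None, knn_k: int = 5, svm_c: float = 1.0):
    """Fit the configured classifier and score a test set.

    Returns (predicted labels, decision scores oriented toward the positive
    class).
    """
    train_y = np.asarray(train_y)
    classes = np.unique(train_y)
    if classes.size != 2:
        raise DegenerateFoldError(
            f"training fold has {classes.size} class(es)"
        )
    if positive is None:
        positive = classes[-1]  # lexicographically larger
    est = make_classifier(spec, knn_k=knn_k, svm_c=svm_c)
    est.fit(np.asarray(train_X, dtype=float), train_y)
    test_X = np.asarray(test_X, dtype=float)
    return est.predict(test_X), decision_scores(est, test_X, positive)


@dataclass
class FoldResult:
    """Counts, metric dict, AUC and selection bookkeeping for one fold."""

    counts: ConfusionCounts
    scores: dict[str, float]
    auc: float
    n_selected: int | None = None
    selected: list[int] | None = None


@dataclass
class EvaluationReport:
    """Per-fold and aggregate cross-validation results."""

    folds: list[FoldResult]
    classifier: str
    seed: int
    positive: str
    n_trials: int
    n_features: int
    selection: bool = False
    extra: dict = field(default_factory=dict)

    @property
    def total_counts(self) -> ConfusionCounts:
        out = ConfusionCounts(0, 0, 0, 0)
        for f in self.folds:
            out = out + f.counts
        return out

    def _values(self, name: str) -> np.ndarray:
        if name == "auc":
            return np.array([f.auc for f in self.folds])
        return np.array([f.scores[name] for f in self.folds])

    def mean(self, name: str) -> float:
        return float(np.nanmean(self._values(name)))

    def sd(self, name: str) -> float:
        return float(np.nanstd(self._values(name)))

    @property
    def accuracy(self) -> float:
        return self.mean("accuracy")

    @property
    def mean_n_selected(self) -> float | None:
        vals = [f.n_selected for f in self.folds if f.n_selected is not None]
        return float(np.mean(vals)) if vals else None

    def summary(self) -> dict[str, float]:
        out = {}
        for name in METRIC_NAMES + ("auc",):
            out[f"{name}_mean"] = self.mean(name)
            out[f"{name}_sd"] = self.sd(name)
        if self.mean_n_selected is not None:
            out["n_selected_mean"] = self.mean_n_selected
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, f in enumerate(self.folds):
            row = {"fold": i, "tp": f.counts.tp, "fn": f.counts.fn,
                   "tn": f.counts.tn, "fp": f.counts.fp, **f.scores,
                   "auc": f.auc}
            if f.n_selected is not None:
                row["n_selected"] = f.n_selected
            rows.append(row)
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = [
            f"classifier: {self.classifier}   folds: {len(self.folds)}   "
            f"seed: {self.seed}   positive: {self.positive}",
            f"trials: {self.n_trials}   features: {self.n_features}   "
            f"nested selection: {self.selection}",
            self.to_frame().to_string(index=False),
            "aggregate (mean +/- sd over folds):",
        ]
        s = self.summary()
        for name in METRIC_NAMES + ("auc",):
            lines.append(f"  {name:12s} {s[name + '_mean']:.4f} "
                         f"+/- {s[name + '_sd']:.4f}")
        if self.mean_n_selected is not None:
            lines.append(f"  selected features per fold (mean): "
                         f"{self.mean_n_selected:.2f}")
        return "\n".join(lines)


def crossvalidate(X, y, spec: str = "svm-linear", folds: int = 10,
                  seed: int = 0, selector=None, positive=None,
                  knn_k: int = 5, svm_c: float = 1.0) -> EvaluationReport:
    """Stratified k-fold cross-validation with optional nested selection.

    The selector (any sklearn SelectorMixin, e.g. HybridSelector) is cloned
    and refit on each training fold before the classifier sees the data, so
    feature selection never touches the test fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=str)
    classes = np.unique(y)
    if classes.size != 2:
        raise StratificationError(f"need two classes, got {classes.size}")
    if positive is None:
        positive = str(classes[-1])
    counts = np.unique(y, return_counts=True)[1]
    if counts.min() < folds:
        raise StratificationError(
            f"minority class has {counts.min()} trials; cannot stratify "
            f"into {folds} folds"
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_results: list[FoldResult] = []
    for train_idx, test_idx in cv.split(X, y):
        Xtr, Xte = X[train_idx], X[test_idx]
        ytr, yte = y[train_idx], y[test_idx]
        n_sel, sel_idx = None, None
        if selector is not None:
            sel = clone(selector).fit(Xtr, ytr)
            mask = sel.get_support()
            sel_idx = list(map(int, np.flatnonzero(mask)))
            n_sel = len(sel_idx)
            if n_sel == 0:  # selector found nothing; fall back to all columns
                sel_idx = list(range(X.shape[1]))
            Xtr, Xte = Xtr[:, sel_idx], Xte[:, sel_idx]
        y_pred, scores = train_predict(Xtr, ytr, Xte, spec=spec,
                                       positive=positive, knn_k=knn_k,
                                       svm_c=svm_c)
        cc = ConfusionCounts.from_labels(yte, y_pred, positive)
        auc = roc_auc(scores, yte, positive=positive)
        fold_results.append(FoldResult(counts=cc, scores=metrics(cc), auc=auc,
                                       n_selected=n_sel, selected=sel_idx))
    return EvaluationReport(
        folds=fold_results, classifier=spec, seed=seed, positive=positive,
        n_trials=len(y), n_features=X.shape[1], selection=selector is not None,
    )
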