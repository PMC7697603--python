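"""Hybrid feature selection: CFS filter pass, then a classifier wrapper.

The selector is a two-stage hybrid:

1. **Correlation-based Feature Selection (CFS)** scores a candidate subset S
   by the merit

       merit(S) = k * r_cf / sqrt(k + k (k-1) * r_ff)

   where k = |S|, r_cf is the mean absolute feature–class correlation
   (point-biserial against the binary label) and r_ff the mean absolute
   pairwise feature–feature Pearson correlation. High class correlation
   raises the merit, redundancy among the chosen features lowers it. The
   subset space is searched best-first from the empty set, expanding the
   most promising subset by one feature at a time and stopping after a fixed
   number of consecutive expansions that fail to improve the best merit
   found (patience, default 5).

2. **Wrapper forward selection** refines the CFS survivors with the actual
   classifier: starting from no features, each round adds the feature whose
   inclusion most improves stratified inner-CV accuracy, accepting only
   strict improvements (ties go to the lowest column index) and stopping at
   the first round with no strictly better addition. Strictness guarantees
   termination and makes the accepted-accuracy trace strictly increasing.

Both stages are deterministic given the input order and the seed that fixes
the inner CV folds. All three selectors are scikit-learn ``SelectorMixin``
estimators, so they nest inside :class:`sklearn.pipeline.Pipeline` and are
refit per training fold under cross-validation (no selection leakage).
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .exceptions import (
    DegenerateDataError,
    DegenerateFoldError,
    NoSignalError,
    ParameterError,
)

__all__ = [
    "SelectionResult",
    "cfs_merit",
    "cfs_filter",
    "wrapper_forward_select",
    "hybrid_select",
    "CFSFilter",
    "ForwardWrapperSelector",
    "HybridSelector",
]


@dataclass
class SelectionResult:
    """Audit record of one hybrid selection run.

    ``selected`` is ordered by wrapper acceptance; all indices refer to the
    columns of the original matrix. ``merit_trace`` is the best CFS merit
    after each best-first expansion; ``wrapper_trace`` the inner-CV accuracy
    after each accepted feature (strictly increasing).
    """

    selected: list[int]
    filter_survivors: list[int]
    merit_trace: list[float]
    wrapper_trace: list[float]
    classifier: str = "svm-linear"
    inner_folds: int = 10
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "selected": [int(i) for i in self.selected],
            "filter_survivors": [int(i) for i in self.filter_survivors],
            "merit_trace": [float(v) for v in self.merit_trace],
            "wrapper_trace": [float(v) for v in self.wrapper_trace],
            "classifier": self.classifier,
            "inner_folds": self.inner_folds,
            "seed": self.seed,
            **self.extra,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def _binary_y01(y) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise DegenerateFoldError(
            f"exactly two classes required, got {classes.size}"
        )
    return (y == classes[1]).astype(float)


def _correlations(X: np.ndarray, y01: np.ndarray):
    """|corr(feature, class)| vector and |corr| feature-feature matrix.

    Constant columns get correlation 0 (they carry no signal) and are
    reported in the returned mask.
    """
    Xc = X - X.mean(axis=0)
    sd = X.std(axis=0)
    ok = sd > 0
    sd_safe = np.where(ok, sd, 1.0)
    Z = Xc / sd_safe
    yc = y01 - y01.mean()
    sy = y01.std()
    if sy == 0:
        raise DegenerateFoldError("single-class labels")
    n = X.shape[0]
    rcf = np.abs(Z.T @ (yc / sy)) / n
    rff = np.abs((Z.T @ Z) / n)
    rcf[~ok] = 0.0
    rff[~ok, :] = 0.0
    rff[:, ~ok] = 0.0
    np.fill_diagonal(rff, 1.0)
    return rcf, rff, ok


def cfs_merit(subset_indices: Sequence[int], X, y) -> float:
    """CFS merit of an explicit feature subset.

    merit = k * mean|r_cf| / sqrt(k + k(k-1) * mean|r_ff|). For a single
    feature this reduces to its absolute class correlation. Constant
    features make the correlations undefined and raise.
    """
    idx = list(subset_indices)
    if not idx:
        raise ParameterError("subset must be non-empty")
    X = np.asarray(X, dtype=float)
    y01 = _binary_y01(y)
    sub = X[:, idx]
    if np.any(sub.std(axis=0) <= 0):
        raise DegenerateDataError("constant feature in subset; correlation undefined")
    rcf, rff, _ = _correlations(sub, y01)
    k = len(idx)
    mean_rcf = rcf.mean()
    if k == 1:
        return float(mean_rcf)
    iu = np.triu_indices(k, 1)
    mean_rff = rff[iu].mean()
    return float(k * mean_rcf / np.sqrt(k + k * (k - 1) * mean_rff))


def _cfs_search(rcf: np.ndarray, rff: np.ndarray, candidates: np.ndarray,
                patience: int):
    """Best-first subset search on precomputed correlations.

    State per subset: (rcf sum, pairwise rff sum). merit = rcf_sum /
    sqrt(k + 2 * rff_pair_sum). Expansion pushes every one-feature child;
    the search stops after `patience` consecutive expansions that do not
    improve the best merit. Ties are broken toward lexicographically
    smaller subsets for determinism.
    """
    best_subset: tuple[int, ...] = ()
    best_merit = 0.0
    merit_trace: list[float] = []
    # heap entries: (-merit, subset tuple, rcf_sum, rff_pair_sum)
    heap: list[tuple[float, tuple[int, ...], float, float]] = [(0.0, (), 0.0, 0.0)]
    visited = {()}
    stale = 0
    while heap and stale < patience:
        neg_merit, subset, rcf_sum, rff_sum = heapq.heappop(heap)
        merit = -neg_merit
        if merit > best_merit:
            best_merit, best_subset = merit, subset
            stale = 0
        else:
            stale += 1
        merit_trace.append(best_merit)
        in_subset = np.zeros(rcf.size, dtype=bool)
        in_subset[list(subset)] = True
        free = candidates[~in_subset[candidates]]
        if free.size == 0:
            continue
        k1 = len(subset) + 1
        rcf_child = rcf_sum + rcf[free]
        rff_add = rff[np.ix_(list(subset), free)].sum(axis=0) if subset \
            else np.zeros(free.size)
        rff_child = rff_sum + rff_add
        merits = rcf_child / np.sqrt(k1 + 2.0 * rff_child)
        for j, f in enumerate(free):
            child = tuple(sorted(subset + (int(f),)))
            if child in visited:
                continue
            visited.add(child)
            heapq.heappush(
                heap, (-float(merits[j]), child,
                       float(rcf_child[j]), float(rff_child[j]))
            )
    return list(best_subset), merit_trace, best_merit


class CFSFilter(SelectorMixin, BaseEstimator):
    """Correlation-based feature-subset filter (best-first search).

    Fitted attributes: ``support_`` boolean mask, ``survivors_`` sorted
    surviving indices, ``merit_trace_`` best merit per expansion,
    ``best_merit_``.

    Parameters
    ----------
    patience : int, default 5
        Consecutive non-improving best-first expansions tolerated before the
        search stops.
    """

    def __init__(self, patience: int = 5):
        self.patience = patience

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ParameterError("X must be 2-D")
        y01 = _binary_y01(y)
        if len(y01) != X.shape[0]:
            raise ParameterError("X and y length mismatch")
        self.n_features_in_ = X.shape[1]
        rcf, rff, ok = _correlations(X, y01)
        candidates = np.flatnonzero(ok)
        if candidates.size == 0:
            raise NoSignalError("all features are constant")
        survivors, trace, best = _cfs_search(rcf, rff, candidates,
                                             self.patience)
        if not survivors:  # no subset beat the empty set; keep the best single
            survivors = [int(candidates[np.argmax(rcf[candidates])])]
        self.survivors_ = sorted(int(i) for i in survivors)
        self.merit_trace_ = trace
        self.best_merit_ = best
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[self.survivors_] = True
        return self

    def _get_support_mask(self) -> np.ndarray:
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags


class ForwardWrapperSelector(SelectorMixin, BaseEstimator):
    """Greedy forward wrapper scored by stratified inner-CV accuracy.

    The baseline is the majority-class rate (the accuracy of a featureless
    classifier); the first feature must strictly beat it. Fitted attributes:
    ``support_``, ``selected_order_`` (acceptance order), ``wrapper_trace_``
    (strictly increasing inner-CV accuracies), ``baseline_``.

    Parameters
    ----------
    estimator : sklearn classifier, optional
        Cloned for every evaluation. Defaults to the linear SVM used by the
        pipeline (see :func:`mibci.evaluation.make_classifier`).
    inner_folds : int, default 10
        Stratified CV folds used to score candidate subsets; the same folds
        are reused for every candidate so comparisons are paired.
    random_state : int, default 0
        Seeds the fold shuffle.
    """

    def __init__(self, estimator=None, inner_folds: int = 10,
                 random_state: int = 0):
        self.estimator = estimator
        self.inner_folds = inner_folds
        self.random_state = random_state

    def _make_estimator(self):
        if self.estimator is not None:
            return clone(self.estimator)
        from .evaluation import make_classifier

        return make_classifier("svm-linear")

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        _binary_y01(y)  # validates two classes
        self.n_features_in_ = X.shape[1]
        counts = np.unique(y, return_counts=True)[1]
        if counts.min() < self.inner_folds:
            raise DegenerateFoldError(
                f"minority class has {counts.min()} samples, fewer than "
                f"{self.inner_folds} inner folds"
            )
        cv = StratifiedKFold(n_splits=self.inner_folds, shuffle=True,
                             random_state=self.random_state)
        folds = list(cv.split(X, y))

        def score(cols: list[int]) -> float:
            est = self._make_estimator()
            accs = cross_val_score(est, X[:, cols], y, cv=folds,
                                   scoring="accuracy", n_jobs=None)
            return float(accs.mean())

        self.baseline_ = float(counts.max() / counts.sum())
        selected: list[int] = []
        trace: list[float] = []
        best = self.baseline_
        remaining = list(range(X.shape[1]))
        while remaining:
            cand_scores = [score(selected + [j]) for j in remaining]
            j_best = int(np.argmax(cand_scores))  # argmax -> lowest index on ties
            if cand_scores[j_best] <= best:
                break
            best = cand_scores[j_best]
            selected.append(remaining.pop(j_best))
            trace.append(best)
        self.selected_order_ = selected
        self.wrapper_trace_ = trace
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[selected] = True
        return self

    def _get_support_mask(self) -> np.ndarray:
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags


class HybridSelector(SelectorMixin, BaseEstimator):
    """CFS filter followed by wrapper forward selection on the survivors.

    Fitted attributes: ``support_`` over the original columns and
    ``selection_result_`` (a :class:`SelectionResult` audit record).

    Parameters
    ----------
    classifier : {"svm-linear", "lda", "knn"}, default "svm-linear"
        Wrapper classifier specification.
    inner_folds : int, default 10
    patience : int, default 5
        CFS best-first patience.
    random_state : int, default 0
    knn_k : int, default 5
    svm_c : float, default 1.0
    """

    def __init__(self, classifier: str = "svm-linear", inner_folds: int = 10,
                 patience: int = 5, random_state: int = 0, knn_k: int = 5,
                 svm_c: float = 1.0):
        self.classifier = classifier
        self.inner_folds = inner_folds
        self.patience = patience
        self.random_state = random_state
        self.knn_k = knn_k
        self.svm_c = svm_c

    def fit(self, X, y):
        from .evaluation import make_classifier

        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.n_features_in_ = X.shape[1]
        cfs = CFSFilter(patience=self.patience).fit(X, y)
        survivors = np.asarray(cfs.survivors_, dtype=int)
        est = make_classifier(self.classifier, knn_k=self.knn_k,
                              svm_c=self.svm_c)
        wrapper = ForwardWrapperSelector(
            estimator=est, inner_folds=self.inner_folds,
            random_state=self.random_state,
        ).fit(X[:, survivors], y)
        selected = [int(survivors[j]) for j in wrapper.selected_order_]
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[selected] = True
        self.selection_result_ = SelectionResult(
            selected=selected,
            filter_survivors=list(map(int, survivors)),
            merit_trace=cfs.merit_trace_,
            wrapper_trace=wrapper.wrapper_trace_,
            classifier=self.classifier,
            inner_folds=self.inner_folds,
            seed=self.random_state,
            extra={"cfs_best_merit": cfs.best_merit_,
                   "wrapper_baseline": wrapper.baseline_},
        )
        return self

    def _get_support_mask(self) -> np.ndarray:
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags


# -- thin functional wrappers ------------------------------------------------

def cfs_filter(X, y, patience: int = 5) -> list[int]:
    """Indices surviving the CFS best-first filter (sorted)."""
    return CFSFilter(patience=patience).fit(X, y).survivors_


def wrapper_forward_select(X, y, classifier_spec: str = "svm-linear",
                           inner_folds: int = 10, seed: int = 0,
                           **clf_kwargs) -> SelectionResult:
    """Forward wrapper selection over all columns of X."""
    from .evaluation import make_classifier

    est = make_classifier(classifier_spec, **clf_kwargs)
    w = ForwardWrapperSelector(estimator=est, inner_folds=inner_folds,
                               random_state=seed).fit(X, y)
    return SelectionResult(
        selected=list(w.selected_order_),
        filter_survivors=list(range(np.asarray(X).shape[1])),
        merit_trace=[],
        wrapper_trace=list(w.wrapper_trace_),
        classifier=classifier_spec,
        inner_folds=inner_folds,
        seed=seed,
        extra={"wrapper_baseline": w.baseline_},
    )


def hybrid_select(X, y, classifier_spec: str = "svm-linear",
                  inner_folds: int = 10, seed: int = 0,
                  patience: int = 5, **clf_kwargs) -> SelectionResult:
    """CFS filter then wrapper refinement; returns the audit record."""
    sel = HybridSelector(classifier=classifier_spec, inner_folds=inner_folds,
                         patience=patience, random_state=seed,
                         **clf_kwargs).fit(X, y)
    return sel.selection_result_
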