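"""CFS merit/filter, wrapper forward selection, and the hybrid selector.

The CFS filter is validated against exhaustive merit maximization over all
subsets of a 10-feature fixture; the wrapper greedy path is validated
against an independent naive re-implementation run on the same folds.
"""

import itertools

import numpy as np
import pytest
from sklearn.model_selection import StratifiedKFold

from mibci import (
    CFSFilter,
    HybridSelector,
    cfs_filter,
    cfs_merit,
    hybrid_select,
    make_classifier,
    wrapper_forward_select,
)
from mibci.exceptions import DegenerateDataError, NoSignalError


def informative_fixture(n=200, n_noise=9, seed=0, r=2.0):
    """One informative column (strongly class-correlated) plus pure noise."""
    rng = np.random.default_rng(seed)
    y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
    rng.shuffle(y)
    y01 = (y == "b").astype(float)
    X = rng.standard_normal((n, 1 + n_noise))
    X[:, 0] = r * y01 + rng.standard_normal(n) * 0.5
    return X, y


def exhaustive_best_subset(X, y, max_k=None):
    """Brute-force merit maximization over every non-empty subset."""
    p = X.shape[1]
    best, best_m = None, -np.inf
    for k in range(1, (max_k or p) + 1):
        for sub in itertools.combinations(range(p), k):
            m = cfs_merit(sub, X, y)
            if m > best_m:
                best, best_m = sub, m
    return set(best), best_m


class TestMerit:
    def test_single_feature_reduces_to_class_correlation(self):
        X, y = informative_fixture(seed=1)
        r = abs(np.corrcoef(X[:, 0], (y == "b").astype(float))[0, 1])
        assert cfs_merit([0], X, y) == pytest.approx(r)

    def test_duplicated_feature_no_merit_gain(self):
        # r_ff = 1: merit(f, f) = 2 r / sqrt(2 + 2) = r = merit(f)
        X, y = informative_fixture(seed=2)
        X2 = np.column_stack([X[:, 0], X[:, 0]])
        assert cfs_merit([0, 1], X2, y) == pytest.approx(
            cfs_merit([0], X2, y))

    def test_independent_feature_merit_near_zero(self):
        rng = np.random.default_rng(3)
        y = np.array(["a", "b"] * 500)
        X = rng.standard_normal((1000, 1))
        assert cfs_merit([0], X, y) < 0.1

    def test_hand_formula_two_features(self):
        """Merit matches the closed form computed from raw correlations."""
        X, y = informative_fixture(seed=4, n_noise=2)
        y01 = (y == "b").astype(float)
        r1 = abs(np.corrcoef(X[:, 0], y01)[0, 1])
        r2 = abs(np.corrcoef(X[:, 1], y01)[0, 1])
        r12 = abs(np.corrcoef(X[:, 0], X[:, 1])[0, 1])
        expected = 2 * ((r1 + r2) / 2) / np.sqrt(2 + 2 * r12)
        assert cfs_merit([0, 1], X, y) == pytest.approx(expected)

    def test_constant_feature_rejected(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        y = np.array(["a", "b"] * 5)
        with pytest.raises(DegenerateDataError):
            cfs_merit([0], X, y)


class TestCFSFilter:
    def test_informative_feature_survives(self):
        X, y = informative_fixture(seed=0)
        survivors = cfs_filter(X, y)
        assert 0 in survivors
        assert len(survivors) < X.shape[1]

    def test_matches_exhaustive_maximization(self):
        X, y = informative_fixture(n=200, n_noise=5, seed=5)
        f = CFSFilter().fit(X, y)
        _, best_m = exhaustive_best_subset(X, y)
        assert f.best_merit_ == pytest.approx(best_m)
        assert set(f.survivors_) == exhaustive_best_subset(X, y)[0]

    def test_duplicated_informative_pair_one_survives(self):
        X, y = informative_fixture(seed=6)
        X = np.column_stack([X, X[:, 0]])  # exact duplicate of the signal
        survivors = cfs_filter(X, y)
        assert not {0, X.shape[1] - 1} <= set(survivors)

    def test_single_feature_input(self):
        X, y = informative_fixture(n_noise=0, seed=7)
        assert cfs_filter(X, y) == [0]

    def test_all_constant_rejected(self):
        X = np.ones((20, 3))
        y = np.array(["a", "b"] * 10)
        with pytest.raises(NoSignalError):
            cfs_filter(X, y)

    def test_merit_trace_recorded(self):
        X, y = informative_fixture(seed=8)
        f = CFSFilter().fit(X, y)
        assert len(f.merit_trace_) >= 1
        assert f.merit_trace_[-1] == pytest.approx(f.best_merit_)


def naive_forward_reference(X, y, folds, spec="svm-linear"):
    """Independent greedy re-implementation for the oracle test."""
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    best = counts.max() / counts.sum()
    selected, remaining = [], list(range(X.shape[1]))
    trace = []
    while remaining:
        scores = []
        for j in remaining:
            accs = []
            for tr, te in folds:
                est = make_classifier(spec)
                cols = selected + [j]
                est.fit(X[np.ix_(tr, cols)], y[tr])
                accs.append(float(
                    (est.predict(X[np.ix_(te, cols)]) == y[te]).mean()))
            scores.append(np.mean(accs))
        jb = int(np.argmax(scores))
        if scores[jb] <= best:
            break
        best = scores[jb]
        selected.append(remaining.pop(jb))
        trace.append(best)
    return selected, trace


class TestWrapper:
    def test_separating_feature_found_and_terminates(self):
        rng = np.random.default_rng(0)
        n = 100
        y = np.array(["a"] * 50 + ["b"] * 50)
        rng.shuffle(y)
        X = rng.standard_normal((n, 6))
        X[:, 2] = np.where(y == "b", 3.0, -3.0) + 0.1 * rng.standard_normal(n)
        res = wrapper_forward_select(X, y, inner_folds=5, seed=0)
        assert res.selected[0] == 2
        assert res.wrapper_trace[-1] == pytest.approx(1.0)

    def test_pure_noise_stays_near_chance(self):
        rng = np.random.default_rng(42)
        n = 200
        y = np.array(["a", "b"] * (n // 2))
        X = rng.standard_normal((n, 8))
        res = wrapper_forward_select(X, y, inner_folds=10, seed=0)
        if res.wrapper_trace:  # nothing selected is also consistent with noise
            ci = 1.96 * np.sqrt(0.25 / n)
            assert res.wrapper_trace[-1] <= 0.5 + 2 * ci

    def test_greedy_path_matches_naive_reference(self):
        X, y = informative_fixture(n=60, n_noise=3, seed=9, r=1.0)
        folds = list(StratifiedKFold(n_splits=5, shuffle=True,
                                     random_state=0).split(X, y))
        ref_sel, ref_trace = naive_forward_reference(X, y, folds)
        res = wrapper_forward_select(X, y, inner_folds=5, seed=0)
        assert res.selected == ref_sel
        np.testing.assert_allclose(res.wrapper_trace, ref_trace)

    def test_trace_strictly_increasing(self):
        X, y = informative_fixture(n=100, n_noise=5, seed=10)
        res = wrapper_forward_select(X, y, inner_folds=5, seed=0)
        t = res.wrapper_trace
        assert all(b > a for a, b in zip(t, t[1:]))


class TestHybrid:
    def test_known_informative_columns_recovered(self):
        rng = np.random.default_rng(11)
        n, p = 200, 120
        y = np.array(["a"] * 100 + ["b"] * 100)
        rng.shuffle(y)
        y01 = (y == "b").astype(float)
        X = rng.standard_normal((n, p))
        informative = [7, 31, 64, 99]
        for j in informative:
            X[:, j] += 1.8 * y01
        res = hybrid_select(X, y, inner_folds=5, seed=0)
        assert 1 <= len(res.selected) < 20
        assert set(res.selected) & set(informative)
        assert set(res.selected) <= set(res.filter_survivors)

    def test_deterministic_given_seed(self):
        X, y = informative_fixture(seed=12)
        r1 = hybrid_select(X, y, inner_folds=5, seed=3)
        r2 = hybrid_select(X, y, inner_folds=5, seed=3)
        assert r1.selected == r2.selected
        assert r1.filter_survivors == r2.filter_survivors
        np.testing.assert_array_equal(r1.wrapper_trace, r2.wrapper_trace)

    def test_sklearn_selector_interface(self):
        X, y = informative_fixture(seed=13)
        sel = HybridSelector(inner_folds=5, random_state=0).fit(X, y)
        Xt = sel.transform(X)
        assert Xt.shape == (X.shape[0], len(sel.selection_result_.selected))
        assert sel.get_support().sum() == Xt.shape[1]

    def test_serialization_round_trip(self, tmp_path):
        import json

        X, y = informative_fixture(seed=14)
        res = hybrid_select(X, y, inner_folds=5, seed=0)
        res.to_json(tmp_path / "sel.json")
        back = json.loads((tmp_path / "sel.json").read_text())
        assert back["selected"] == res.selected
        assert back["classifier"] == "svm-linear"


def test_nested_selection_no_leakage():
    """With permuted labels, outer-CV accuracy of the full select+classify
    pipeline stays at chance: selection inside the training folds cannot
    leak test labels."""
    from mibci import crossvalidate

    rng = np.random.default_rng(21)
    n, p = 80, 40
    X = rng.standard_normal((n, p))
    y = np.array(["a", "b"] * (n // 2))  # labels independent of X
    sel = HybridSelector(inner_folds=5, random_state=0)
    rep = crossvalidate(X, y, folds=5, seed=0, selector=sel)
    ci = 1.96 * np.sqrt(0.25 / n)
    assert abs(rep.total_counts.tp + rep.total_counts.tn - n / 2) / n <= 2 * ci
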