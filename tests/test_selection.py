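import numpy as np
import pandas as pd
import pytest

from glioresponse.classify import train_linear
from glioresponse.selection import (
    FeatureTable,
    embedded_relevance,
    embedded_rfe,
    hybrid_embedded_then_wrapper,
    ttest_rank,
    wrapper_rfe,
)


def _table(X, y, subjects=None):
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    if subjects is None:
        subjects = np.array([f"s{i}" for i in range(len(y))])
    return FeatureTable(df, np.asarray(y), subjects)


def _informative_table(rng, n=60, effect=3.0, n_noise=1):
    y = np.where(rng.random(n) < 0.5, 1, -1)
    cols = [y * effect / 2 + rng.standard_normal(n) for _ in range(2)]
    cols += [rng.standard_normal(n) for _ in range(n_noise)]
    return _table(np.column_stack(cols), y)


class TestTtestRank:
    def test_constant_feature_last_score_zero(self):
        rng = np.random.default_rng(0)
        y = np.array([1, 1, 1, -1, -1, -1])
        X = np.column_stack([rng.normal(size=6), np.full(6, 3.0)])
        rank = ttest_rank(_table(X, y))
        assert rank.features[-1] == "f1"
        assert rank.scores[-1] == 0.0

    def test_label_feature_first(self):
        rng = np.random.default_rng(1)
        y = np.array([1, 1, 1, -1, -1, -1])
        X = np.column_stack([rng.normal(size=6), y.astype(float)])
        rank = ttest_rank(_table(X, y))
        assert rank.features[0] == "f1"

    def test_welch_formula(self):
        # fixed 6x3 table; expected |t| from the Welch formula evaluated inline
        X = np.array([
            [1.0, 10.0, 0.5],
            [2.0, 11.0, 0.6],
            [3.0, 12.0, 0.4],
            [4.0, 20.0, 0.5],
            [5.0, 21.0, 0.7],
            [6.0, 19.0, 0.3],
        ])
        y = np.array([1, 1, 1, -1, -1, -1])
        rank = ttest_rank(_table(X, y))
        scores = dict(zip(rank.features, rank.scores))
        for j in range(3):
            a, b = X[:3, j], X[3:, j]
            se = np.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
            expected = abs((a.mean() - b.mean()) / se)
            assert scores[f"f{j}"] == pytest.approx(expected)

    def test_requires_two_classes(self):
        with pytest.raises(ValueError):
            ttest_rank(_table(np.ones((4, 2)), np.ones(4)))


class TestEmbeddedRelevance:
    def test_single_model_absolute_values(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 3)),
                         columns=["a", "b", "c"])
        y = np.where(np.arange(20) % 2 == 0, 1, -1)
        m = train_linear(X, y, "LR")
        m.weights = pd.Series([3.0, -1.0, 0.5], index=["a", "b", "c"])
        rel = embedded_relevance([m])
        assert list(rel) == [3.0, 1.0, 0.5]

    def test_sign_cancellation_does_not_reduce(self):
        X = pd.DataFrame(np.zeros((2, 2)), columns=["a", "b"])
        y = np.array([1, -1])
        m1 = train_linear(pd.DataFrame(np.random.default_rng(1).normal(size=(10, 2)),
                                       columns=["a", "b"]),
                          np.where(np.arange(10) % 2 == 0, 1, -1), "LR")
        m2 = train_linear(pd.DataFrame(np.random.default_rng(2).normal(size=(10, 2)),
                                       columns=["a", "b"]),
                          np.where(np.arange(10) % 2 == 0, 1, -1), "LR")
        m1.weights = pd.Series([1.0, -1.0], index=["a", "b"])
        m2.weights = pd.Series([-1.0, 1.0], index=["a", "b"])
        rel = embedded_relevance([m1, m2])
        assert list(rel) == [1.0, 1.0]

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        y = np.where(X["a"] > 0, 1, -1)
        m = train_linear(X, y, "LR")
        Xf = X.copy()
        Xf["b"] = -Xf["b"]
        mf = train_linear(Xf, y, "LR")
        r1 = embedded_relevance([m])
        r2 = embedded_relevance([mf])
        np.testing.assert_allclose(r1.to_numpy(), r2.to_numpy(), atol=1e-6)

    def test_manifest_mismatch_fails(self):
        rng = np.random.default_rng(4)
        y = np.where(np.arange(12) % 2 == 0, 1, -1)
        m1 = train_linear(pd.DataFrame(rng.normal(size=(12, 2)), columns=["a", "b"]), y, "LR")
        m2 = train_linear(pd.DataFrame(rng.normal(size=(12, 2)), columns=["a", "c"]), y, "LR")
        with pytest.raises(ValueError):
            embedded_relevance([m1, m2])


class TestEmbeddedRFE:
    def test_elimination_order_complete(self):
        rng = np.random.default_rng(0)
        t = _informative_table(rng, n=40)
        rank = embedded_rfe(t, "LR", k_folds=4, seed=0)
        assert sorted(rank.features) == sorted(t.feature_names)
        assert rank.nested

    def test_nested_subsets(self):
        rng = np.random.default_rng(1)
        t = _informative_table(rng, n=40, n_noise=3)
        rank = embedded_rfe(t, "LR", k_folds=4, seed=0)
        for m in range(1, len(t.feature_names)):
            assert set(rank.subsets[m]) <= set(rank.subsets[m + 1])

    def test_noise_eliminated_first_mostly(self):
        hits = 0
        reps = 25
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            t = _informative_table(rng, n=200, effect=3.0, n_noise=1)
            rank = embedded_rfe(t, "LR", k_folds=5, seed=rep)
            # noise column is f2; eliminated first == last in relevance order
            if rank.features[-1] == "f2":
                hits += 1
        assert hits / reps >= 0.9

    def test_constant_feature_eliminated_first(self):
        rng = np.random.default_rng(2)
        y = np.where(rng.random(40) < 0.5, 1, -1)
        X = np.column_stack([y * 2.0 + rng.standard_normal(40), np.full(40, 7.0)])
        t = _table(X, y)
        rank = embedded_rfe(t, "LR", k_folds=4, seed=0)
        assert rank.features[-1] == "f1"


class TestWrapperRFE:
    def test_anti_informative_removed_first(self):
        rng = np.random.default_rng(0)
        n = 80
        y = np.where(rng.random(n) < 0.5, 1, -1)
        good1 = y * 2.0 + rng.standard_normal(n)
        good2 = y * 2.0 + rng.standard_normal(n)
        # anti-informative: label-dependent but with per-class overlap flipped
        anti = rng.permutation(y) * 2.0 + rng.standard_normal(n)
        t = _table(np.column_stack([good1, good2, anti]), y)
        rank = wrapper_rfe(t, "LR", cv=4, seed=0)
        assert rank.features[-1] == "f2"
        # removal of the useless feature cannot hurt the trace
        assert rank.accuracy_trace[2] >= rank.accuracy_trace[3] - 1e-9

    def test_full_set_accuracy_is_plain_cv(self):
        from glioresponse.classify import cv_evaluate

        rng = np.random.default_rng(1)
        t = _informative_table(rng, n=40)
        rank = wrapper_rfe(t, "LR", cv=4, seed=0)
        res = cv_evaluate(t.X, t.labels, "LR", 4, groups=t.subjects, seed=0)
        assert rank.accuracy_trace[len(t.feature_names)] == pytest.approx(res.accuracy)

    def test_nested_and_terminates_at_one(self):
        rng = np.random.default_rng(2)
        t = _informative_table(rng, n=40, n_noise=2)
        rank = wrapper_rfe(t, "LR", cv=4, seed=0)
        assert set(rank.subsets) == set(range(1, 5))
        for m in range(1, 4):
            assert set(rank.subsets[m]) <= set(rank.subsets[m + 1])
        assert len(rank.subsets[1]) == 1


class TestHybrid:
    def test_m_equals_feature_count_is_wrapper(self):
        rng = np.random.default_rng(0)
        t = _informative_table(rng, n=40, n_noise=2)
        hyb = hybrid_embedded_then_wrapper(t, "LR", k_folds=4, cv=4,
                                           m=len(t.feature_names), seed=0)
        assert set(hyb.subsets) == set(range(1, len(t.feature_names) + 1))

    def test_wrapper_search_space_truncated(self):
        rng = np.random.default_rng(1)
        t = _informative_table(rng, n=50, n_noise=6)
        hyb = hybrid_embedded_then_wrapper(t, "LR", k_folds=4, cv=4, m=3, seed=0)
        assert max(hyb.subsets) == 3

    def test_m_too_large_fails(self):
        rng = np.random.default_rng(2)
        t = _informative_table(rng, n=30)
        with pytest.raises(ValueError):
            hybrid_embedded_then_wrapper(t, "LR", m=99, seed=0)

    def test_planted_features_recovered(self):
        hits = 0
        reps = 10
        for rep in range(reps):
            rng = np.random.default_rng(200 + rep)
            t = _informative_table(rng, n=120, effect=3.0, n_noise=4)
            hyb = hybrid_embedded_then_wrapper(t, "LR", k_folds=4, cv=4, m=4,
                                               seed=rep)
            if {"f0", "f1"} <= set(hyb.subsets[2]):
                hits += 1
        assert hits / reps >= 0.9


class TestSchemeAgreement:
    def test_perfect_single_feature_first_in_all_schemes(self):
        rng = np.random.default_rng(3)
        n = 40
        y = np.where(np.arange(n) % 2 == 0, 1, -1)
        X = np.column_stack([y * 5.0, rng.standard_normal(n), rng.standard_normal(n)])
        t = _table(X, y)
        assert ttest_rank(t).features[0] == "f0"
        assert embedded_rfe(t, "LR", k_folds=4, seed=0).features[0] == "f0"
        assert wrapper_rfe(t, "LR", cv=4, seed=0).features[0] == "f0"
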