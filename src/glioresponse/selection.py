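"""Feature ranking and pruning: t-test filter, embedded RFE, wrapper RFE.

All three schemes operate on a :class:`FeatureTable` whose rows are samples
(slices for MRI, voxels for MRSI) grouped by subject. Cross-validation folds
are grouped by subject by default so that no subject leaks across folds;
``grouped=False`` reproduces naive per-row folding.

Features are z-scored with train-fold statistics before any weight-magnitude
comparison — absolute-weight relevance is meaningless on unscaled features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from glioresponse.classify import cv_evaluate, train_linear


@dataclass
class FeatureTable:
    """Named feature columns x sample rows with subject grouping and labels."""

    X: pd.DataFrame
    labels: np.ndarray      # +1 treated / -1 control per row
    subjects: np.ndarray    # subject id per row

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.subjects = np.asarray(self.subjects)
        if len(self.X) != len(self.labels) or len(self.X) != len(self.subjects):
            raise ValueError("row count mismatch")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def subset(self, names: list[str]) -> "FeatureTable":
        return FeatureTable(self.X[names], self.labels, self.subjects)


@dataclass
class RelevanceRanking:
    """Features ordered most-relevant-first, with per-feature scores."""

    features: list[str]
    scores: list[float]
    scheme: str
    nested: bool = False
    #: subsets[m] = the m most relevant features (RFE output only)
    subsets: dict[int, list[str]] = field(default_factory=dict)
    #: accuracy_trace[m] = CV accuracy of the best m-feature subset (wrapper)
    accuracy_trace: dict[int, float] = field(default_factory=dict)


def ttest_rank(table: FeatureTable, labels: np.ndarray | None = None
               ) -> RelevanceRanking:
    """Welch two-sample t-test per feature, ranked by |t| descending.

    A feature with zero variance in both classes scores 0 (ranked last);
    zero-variance but different means scores +inf (perfect separation).
    Ties break deterministically by feature name.
    """
    y = table.labels if labels is None else np.asarray(labels)
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    a_mask, b_mask = y > 0, y <= 0
    if a_mask.sum() < 2 or b_mask.sum() < 2:
        raise ValueError("need >= 2 samples per class")
    scores = {}
    for name in table.feature_names:
        x = table.X[name].to_numpy(dtype=float)
        a, b = x[a_mask], x[b_mask]
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            scores[name] = 0.0 if a.mean() == b.mean() else np.inf
        else:
            t, _ = stats.ttest_ind(a, b, equal_var=False)
            scores[name] = float(abs(t))
    order = sorted(scores, key=lambda k: (-scores[k], k))
    return RelevanceRanking(
        features=order, scores=[scores[k] for k in order], scheme="ttest"
    )


def embedded_relevance(models: list) -> pd.Series:
    """Mean absolute weight per feature across K fitted linear models."""
    if not models:
        raise ValueError("no models")
    names = list(models[0].weights.index)
    for m in models[1:]:
        if list(m.weights.index) != names:
            raise ValueError("models do not share a feature manifest")
    stacked = np.vstack([m.weights.to_numpy() for m in models])
    return pd.Series(np.mean(np.abs(stacked), axis=0), index=names)


def _grouped_folds(y: np.ndarray, groups: np.ndarray, k: int, seed: int,
                   grouped: bool = True) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k folds over subjects (or rows), each fold-train two-class."""
    rng = np.random.default_rng(seed)
    units = np.unique(groups) if grouped else np.arange(len(y))
    unit_of = groups if grouped else np.arange(len(y))
    unit_label = {}
    for u in units:
        unit_label[u] = int(np.sign(np.mean(y[unit_of == u])) or 1)
    for attempt in range(50):
        fold_of = {}
        for lbl in (-1, +1):
            mem = [u for u in units if unit_label[u] == lbl]
            rng.shuffle(mem)
            for i, u in enumerate(mem):
                fold_of[u] = i % k
        folds = []
        ok = True
        for f in range(k):
            test = np.array([fold_of[u] == f for u in unit_of])
            train = ~test
            if not test.any() or len(np.unique(y[train])) < 2:
                ok = False
                break
            folds.append((np.nonzero(train)[0], np.nonzero(test)[0]))
        if ok:
            return folds
    raise ValueError("could not build stratified folds with two-class train splits")


def embedded_rfe(table: FeatureTable, model_type: str = "LR", k_folds: int = 5,
                 seed: int = 0, grouped: bool = True) -> RelevanceRanking:
    """Recursive elimination of the feature with smallest mean |weight|.

    At each step K linear models are trained on stratified fold-train splits
    (z-scored inside the model pipeline) and the feature whose mean absolute
    weight is smallest is removed. Subsets of every size are nested by
    construction.
    """
    remaining = list(table.feature_names)
    eliminated: list[str] = []
    subsets: dict[int, list[str]] = {len(remaining): list(remaining)}
    folds = _grouped_folds(table.labels, table.subjects, k_folds, seed, grouped)
    while len(remaining) > 1:
        sub = table.subset(remaining)
        models = [
            train_linear(sub.X.iloc[tr], sub.labels[tr], model_type)
            for tr, _ in folds
        ]
        rel = embedded_relevance(models)
        victim = min(remaining, key=lambda f: (rel[f], f))
        eliminated.append(victim)
        remaining = [f for f in remaining if f != victim]
        subsets[len(remaining)] = list(remaining)
    eliminated.append(remaining[0])
    order = eliminated[::-1]  # most relevant first
    return RelevanceRanking(
        features=order,
        scores=list(range(len(order), 0, -1)),
        scheme="embedded_rfe",
        nested=True,
        subsets=subsets,
    )


def wrapper_rfe(table: FeatureTable, model_type: str = "SVM",
                cv: str | int = "loo", seed: int = 0,
                grouped: bool = True) -> RelevanceRanking:
    """Recursive elimination driven by cross-validated accuracy.

    At each step the CV accuracy is evaluated with every single remaining
    feature removed; the feature whose removal yields the highest accuracy is
    eliminated. Ties break by lower univariate |t|, then by name. The trace
    records the accuracy of the surviving subset at every size, including the
    full set (= plain CV accuracy of the classifier).
    """
    tstat = dict(zip(*(lambda r: (r.features, r.scores))(ttest_rank(table))))
    remaining = list(table.feature_names)
    eliminated: list[str] = []
    subsets: dict[int, list[str]] = {len(remaining): list(remaining)}
    trace: dict[int, float] = {}
    full = cv_evaluate(table.X, table.labels, model_type, cv,
                       groups=table.subjects if grouped else None, seed=seed)
    trace[len(remaining)] = full.accuracy
    while len(remaining) > 1:
        best_feat, best_acc = None, -1.0
        for f in sorted(remaining, key=lambda f: (tstat.get(f, 0.0), f)):
            trial = [g for g in remaining if g != f]
            res = cv_evaluate(table.X[trial], table.labels, model_type, cv,
                              groups=table.subjects if grouped else None,
                              seed=seed)
            if res.accuracy > best_acc:
                best_feat, best_acc = f, res.accuracy
        eliminated.append(best_feat)
        remaining = [g for g in remaining if g != best_feat]
        subsets[len(remaining)] = list(remaining)
        trace[len(remaining)] = best_acc
    eliminated.append(remaining[0])
    order = eliminated[::-1]
    return RelevanceRanking(
        features=order,
        scores=[trace.get(i + 1, np.nan) for i in range(len(order))],
        scheme="wrapper_rfe",
        nested=True,
        subsets=subsets,
        accuracy_trace=trace,
    )


def hybrid_embedded_then_wrapper(
    table: FeatureTable, model_type: str = "LR", k_folds: int = 5,
    cv: str | int = "loo", m: int = 30, seed: int = 0,
    grouped: bool = True,
) -> RelevanceRanking:
    """Embedded RFE keeps the top-m features; wrapper RFE refines within them."""
    if m > len(table.feature_names):
        raise ValueError("m exceeds feature count")
    emb = embedded_rfe(table, model_type, k_folds, seed, grouped)
    top_m = emb.subsets[m] if m in emb.subsets else emb.features[:m]
    wrap = wrapper_rfe(table.subset(top_m), model_type, cv, seed, grouped)
    wrap.scheme = "hybrid"
    return wrap
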