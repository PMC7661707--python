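"""Linear classifiers, grouped cross-validation, and SVS/VVS vote fusion.

Label encoding is fixed across the codebase: control = -1, treated = +1,
with treated as the positive class. Decision scores ``s = w·x + b`` are
taken in the z-scored feature space (scaling is part of every model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

MODEL_TYPES = ("LR", "LDA", "SVM")


@dataclass
class ClassifierModel:
    """A fitted linear decision rule ``f(x) = g(w·x + b)``."""

    weights: pd.Series
    intercept: float
    link: str                   # "logistic" for LR, "identity" otherwise
    model_type: str
    pipeline: Pipeline

    def decision_scores(self, X: pd.DataFrame) -> np.ndarray:
        return self.pipeline.decision_function(X)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Signed labels: +1 treated, -1 control."""
        return np.where(self.decision_scores(X) >= 0, 1, -1)


@dataclass
class CVResult:
    accuracy: float
    scores: np.ndarray          # out-of-fold decision score per sample
    predictions: np.ndarray     # signed labels


@dataclass
class SubjectDecision:
    subject_id: str
    method: str                 # SVS | VVS | single-slice
    fused: float                # fraction (weighted) toward treated, in [0, 1]
    label: int                  # +1 / -1
    tallies: dict = field(default_factory=dict)


def _make_estimator(model_type: str, seed: int = 0) -> Pipeline:
    if model_type == "LR":
        est = LogisticRegression(C=1.0, max_iter=2000, random_state=seed)
    elif model_type == "LDA":
        est = LinearDiscriminantAnalysis()
    elif model_type == "SVM":
        est = SVC(kernel="linear", C=1.0, random_state=seed)
    else:
        raise ValueError(f"unknown model_type {model_type!r}; use one of {MODEL_TYPES}")
    return Pipeline([("scale", StandardScaler()), ("clf", est)])


def train_linear(X: pd.DataFrame, y: np.ndarray, model_type: str = "LR",
                 seed: int = 0) -> ClassifierModel:
    """Fit one linear model (with internal z-scoring) on signed labels."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class training set")
    pipe = _make_estimator(model_type, seed)
    pipe.fit(X, y)
    clf = pipe.named_steps["clf"]
    w = np.ravel(clf.coef_)
    b = float(np.ravel(clf.intercept_)[0])
    return ClassifierModel(
        weights=pd.Series(w, index=list(X.columns)),
        intercept=b,
        link="logistic" if model_type == "LR" else "identity",
        model_type=model_type,
        pipeline=pipe,
    )


def _fold_assignment(y: np.ndarray, groups: np.ndarray, k: int,
                     seed: int) -> np.ndarray:
    """Stratified assignment of groups to k folds; returns fold id per row."""
    rng = np.random.default_rng(seed)
    units = np.unique(groups)
    fold_of = {}
    for lbl in np.unique([int(np.sign(np.mean(y[groups == u])) or 1) for u in units]):
        mem = [u for u in units
               if int(np.sign(np.mean(y[groups == u])) or 1) == lbl]
        rng.shuffle(mem)
        for i, u in enumerate(mem):
            fold_of[u] = i % k
    return np.array([fold_of[g] for g in groups])


def cv_evaluate(X: pd.DataFrame, y: np.ndarray, model_type: str = "LR",
                protocol: str | int = "loo", groups: np.ndarray | None = None,
                seed: int = 0) -> CVResult:
    """Grouped cross-validation returning out-of-fold scores for every sample.

    ``protocol`` is ``"loo"`` (leave one group out) or an integer k for
    k-fold. With ``groups=None`` every row is its own group.
    """
    y = np.asarray(y)
    if groups is None:
        groups = np.arange(len(y))
    groups = np.asarray(groups)
    units = np.unique(groups)
    if protocol == "loo":
        fold_ids = np.array([np.searchsorted(units, g) for g in groups])
        n_folds = len(units)
    else:
        k = int(protocol)
        if k > len(units):
            raise ValueError(f"k={k} exceeds number of groups ({len(units)})")
        fold_ids = _fold_assignment(y, groups, k, seed)
        n_folds = k
    scores = np.full(len(y), np.nan)
    for f in range(n_folds):
        test = fold_ids == f
        train = ~test
        if not test.any():
            continue
        if len(np.unique(y[train])) < 2:
            raise ValueError("degenerate fold: single-class training split")
        model = train_linear(X.loc[train], y[train], model_type, seed)
        scores[test] = model.decision_scores(X.loc[test])
    preds = np.where(scores >= 0, 1, -1)
    return CVResult(accuracy=float(np.mean(preds == y)), scores=scores,
                    predictions=preds)


def svs_vote(responses: np.ndarray, weights: np.ndarray,
             subject_id: str = "") -> SubjectDecision:
    """Slice-voting: mask-size-weighted average of per-slice responses.

    ``responses`` are in [0, 1] (binary labels or calibrated scores);
    ``weights`` are the tumor-mask pixel counts. The subject is called
    treated iff the fused value >= 0.5 (ties go to treated).
    """
    responses = np.asarray(responses, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if responses.size == 0:
        raise ValueError("no slice responses to fuse")
    if np.all(weights == 0):
        raise ValueError("all-zero slice weights")
    if (weights < 0).any():
        raise ValueError("negative slice weight")
    fused = float(np.sum(weights * responses) / np.sum(weights))
    label = 1 if fused >= 0.5 else -1
    return SubjectDecision(
        subject_id=subject_id, method="SVS" if responses.size > 1 else "single-slice",
        fused=fused, label=label,
        tallies={"responses": responses.tolist(), "weights": weights.tolist()},
    )


def vvs_vote(voxel_labels: np.ndarray, subject_id: str = "") -> SubjectDecision:
    """Voxel-voting: majority over signed voxel labels across all slices.

    The fused value is the fraction of voxels called treated; a tie goes
    to treated.
    """
    voxel_labels = np.asarray(voxel_labels)
    if voxel_labels.size == 0:
        raise ValueError("no classified voxels")
    n_treated = int(np.sum(voxel_labels > 0))
    n_control = int(voxel_labels.size - n_treated)
    fused = n_treated / voxel_labels.size
    label = 1 if n_treated >= n_control else -1
    return SubjectDecision(
        subject_id=subject_id, method="VVS", fused=fused, label=label,
        tallies={"treated": n_treated, "control": n_control},
    )
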