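"""Linear SVM recursive feature elimination for stock classification.

Candidate features are the union of the two stocks' core DEG sets. The
ranking loop fits a linear soft-margin SVM (C = 1), scores each feature by
|w_j| multiplied by the absolute two-sample t-statistic of the feature
computed on the current support vectors (a sigFeature-style composite;
plain |w| SVM-RFE is available via ``mode="svmrfe"``), and eliminates the
lowest-scoring ~10% per round; the reverse elimination order is the
ranking. Classifier performance is scored by EXTERNAL stratified ten-fold
cross-validation: standardization and the ranking itself are recomputed on
each training split, so the error curve never sees the held-out fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .setops import DEGSet, union_sets


@dataclass
class SVMTrace:
    k_grid: list[int]
    cv_error_mean: np.ndarray
    cv_error_sd: np.ndarray
    ranking: list[str]  # best feature first
    fold_assignments: pd.Series | None = None


def candidate_features(degsets_by_stock: Mapping[str, DEGSet]) -> set[str]:
    """Union of the per-stock core DEG sets."""
    sets = list(degsets_by_stock.values())
    if len(sets) < 2:
        raise ValueError("need core DEG sets for both stocks")
    union = union_sets(sets).genes
    if not union:
        raise ValueError("union of DEG sets is empty")
    return union


def _standardize(train: np.ndarray, other: np.ndarray | None = None):
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    if other is None:
        return (train - mean) / sd
    return (train - mean) / sd, (other - mean) / sd


def _sv_tstat(Xs: np.ndarray, y01: np.ndarray, sv_idx: np.ndarray) -> np.ndarray:
    """Absolute two-sample t per feature on the support vectors.

    Falls back to all samples when the support vectors miss a class.
    """
    rows = sv_idx
    if len(np.unique(y01[rows])) < 2 or min(np.bincount(y01[rows])) < 2:
        rows = np.arange(len(y01))
    a = Xs[rows][y01[rows] == 0]
    b = Xs[rows][y01[rows] == 1]
    va = a.var(axis=0, ddof=1) / len(a)
    vb = b.var(axis=0, ddof=1) / len(b)
    denom = np.sqrt(va + vb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (a.mean(axis=0) - b.mean(axis=0)) / denom, 0.0)
    return np.abs(t)


def svm_rfe_rank(
    X: pd.DataFrame,
    labels: Sequence[str],
    step_fraction: float = 0.1,
    C: float = 1.0,
    mode: str = "sigfeature",
    seed: int = 0,
) -> list[str]:
    """Rank features by recursive linear-SVM elimination (best first).

    Per round, score = |w_j| (mode "svmrfe") or |w_j| * |t_j on support
    vectors| (mode "sigfeature"); the lowest ceil(step_fraction * current)
    features are eliminated, ties broken toward the smaller column index.
    """
    y = pd.Series(labels).astype(str)
    classes = sorted(y.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    y01 = (y == classes[1]).to_numpy().astype(int)
    if mode not in ("sigfeature", "svmrfe"):
        raise ValueError(f"unknown mode {mode!r}")
    cols = list(X.columns)
    col_pos = {c: i for i, c in enumerate(cols)}
    arr = X.to_numpy(dtype=float)
    remaining = list(cols)
    eliminated: list[str] = []
    while remaining:
        idx = [col_pos[c] for c in remaining]
        Xs = _standardize(arr[:, idx])
        clf = SVC(kernel="linear", C=C, random_state=seed)
        clf.fit(Xs, y01)
        w = np.abs(clf.coef_.ravel())
        if mode == "sigfeature":
            score = w * _sv_tstat(Xs, y01, clf.support_)
        else:
            score = w
        n_drop = min(len(remaining), max(1, math.ceil(step_fraction * len(remaining))))
        # worst first; equal scores drop the larger original index first so
        # the reversed ranking prefers the smaller index
        order = np.lexsort((-np.arange(len(remaining)), score))
        dropped = [remaining[i] for i in order[:n_drop]]
        eliminated.extend(dropped)
        dropped_set = set(dropped)
        remaining = [c for c in remaining if c not in dropped_set]
    return eliminated[::-1]


def external_cv_curve(
    X: pd.DataFrame,
    labels: Sequence[str],
    k_grid: Sequence[int] | None = None,
    folds: int = 10,
    seed: int = 0,
    step_fraction: float = 0.1,
    C: float = 1.0,
    mode: str = "sigfeature",
    ranking: Sequence[str] | None = None,
) -> SVMTrace:
    """External stratified CV of the RFE-reduced SVM at each panel size k.

    For every fold the feature ranking and the standardization are refit on
    the training split only. ``SVMTrace.ranking`` is the full-data ranking
    (recomputed here unless supplied), which is what gets reported as "the"
    feature list; the error curve remains externally validated.
    """
    y = pd.Series(labels).astype(str).reset_index(drop=True)
    classes = sorted(y.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    y01 = (y == classes[1]).to_numpy().astype(int)
    min_class = min(np.bincount(y01))
    if folds > min_class:
        raise ValueError(f"{folds} folds but smallest class has {min_class} samples")
    p = X.shape[1]
    if k_grid is None:
        k_grid = sorted({k for k in (1, 2, 5, 10, 20, 50, 100, 200, 500, p) if 1 <= k <= p})
    else:
        k_grid = sorted(set(int(k) for k in k_grid))
        if any(k < 1 or k > p for k in k_grid):
            raise ValueError("k_grid values must be in [1, n_features]")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    arr = X.to_numpy(dtype=float)
    errors = np.zeros((folds, len(k_grid)))
    fold_of = np.zeros(len(y01), dtype=int)
    for f, (tr, te) in enumerate(skf.split(arr, y01)):
        fold_of[te] = f
        if len(np.unique(y01[te])) < 2:
            raise ValueError(f"fold {f} lacks both classes")
        fold_rank = svm_rfe_rank(
            X.iloc[tr], y.iloc[tr], step_fraction=step_fraction, C=C, mode=mode, seed=seed
        )
        for ki, k in enumerate(k_grid):
            feats = [X.columns.get_loc(c) for c in fold_rank[:k]]
            Xtr, Xte = _standardize(arr[np.ix_(tr, feats)], arr[np.ix_(te, feats)])
            clf = SVC(kernel="linear", C=C, random_state=seed)
            clf.fit(Xtr, y01[tr])
            errors[f, ki] = np.mean(clf.predict(Xte) != y01[te])
    if ranking is None:
        ranking = svm_rfe_rank(X, y, step_fraction=step_fraction, C=C, mode=mode, seed=seed)
    return SVMTrace(
        k_grid=list(k_grid),
        cv_error_mean=errors.mean(axis=0),
        cv_error_sd=errors.std(axis=0, ddof=1),
        ranking=list(ranking),
        fold_assignments=pd.Series(fold_of, index=X.index),
    )


def select_top_features(trace: SVMTrace, k: int = 20) -> list[str]:
    """First k entries of the full-data ranking."""
    if k > len(trace.ranking):
        raise ValueError(f"k={k} exceeds ranking length {len(trace.ranking)}")
    return trace.ranking[:k]
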