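"""Leading-logFC MDS, correlation clustering and the CV contrast.

The between-sample distance is the "leading log fold change": for each pair
of samples, the root-mean-square of the ``top`` largest absolute expression
differences, recomputed per pair (pairwise mode). Classical (Torgerson)
multidimensional scaling of that distance matrix places samples so that
diet separation dominates the first axis when the diet program is the
largest source of variation. Hierarchical clustering uses 1 - Pearson r
with average linkage. The coefficient-of-variation comparison contrasts
per-gene within-group CVs between two groups with a Welch two-sample t.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import ExprMatrix


@dataclass
class DistanceMatrix:
    sample_ids: pd.Index
    d: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(self.d)).max() > 1e-12:
            raise ValueError("distance matrix must have zero diagonal")
        if (self.d < -1e-12).any():
            raise ValueError("distances must be non-negative")


@dataclass
class MDSResult:
    coordinates: pd.DataFrame  # samples x k
    var_explained: np.ndarray  # per retained dimension
    negative_eigenvalues_truncated: int = 0


class CVReport(NamedTuple):
    cv: pd.DataFrame  # genes x 2 groups, per-gene within-group CV
    t: float
    df: float
    p: float
    dropped_genes: int


def leading_logfc_distance(expr: ExprMatrix, top: int = 300) -> DistanceMatrix:
    """Pairwise RMS of the ``top`` largest per-pair expression differences."""
    if top <= 0:
        raise ValueError("top must be positive")
    X = expr.values.to_numpy()
    G, N = X.shape
    top = min(top, G)
    d = np.zeros((N, N))
    for i in range(N):
        for j in range(i + 1, N):
            diff_sq = (X[:, i] - X[:, j]) ** 2
            if top < G:
                sel = np.partition(diff_sq, G - top)[G - top :]
            else:
                sel = diff_sq
            d[i, j] = d[j, i] = np.sqrt(sel.mean())
    return DistanceMatrix(sample_ids=expr.sample_ids, d=d)


def classical_mds(dist: DistanceMatrix, k: int = 2) -> MDSResult:
    """Torgerson MDS: double-center -d^2/2, take the top-k eigenpairs.

    Variance explained is relative to the sum of positive eigenvalues;
    negative eigenvalues (non-Euclidean distances) are truncated and
    counted. Axis signs fixed so each axis's first nonzero loading is
    positive.
    """
    n = dist.d.shape[0]
    if not 0 < k < n:
        raise ValueError("need 0 < k < n_samples")
    D2 = dist.d**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12, 1e-12 * abs(evals).max())
    n_neg = int((evals < -max(1e-12, 1e-12 * abs(evals).max())).sum())
    total_pos = evals[pos].sum()
    if total_pos <= 0:
        coords = np.zeros((n, k))
        return MDSResult(
            coordinates=pd.DataFrame(
                coords, index=dist.sample_ids, columns=[f"dim{i+1}" for i in range(k)]
            ),
            var_explained=np.full(k, np.nan),
            negative_eigenvalues_truncated=n_neg,
        )
    k_eff = min(k, int(pos.sum()))
    lam = evals[:k_eff]
    V = evecs[:, :k_eff]
    coords = V * np.sqrt(lam)[None, :]
    for a in range(k_eff):
        nz = np.nonzero(np.abs(coords[:, a]) > 1e-12)[0]
        if nz.size and coords[nz[0], a] < 0:
            coords[:, a] = -coords[:, a]
    if k_eff < k:
        coords = np.hstack([coords, np.zeros((n, k - k_eff))])
    var_explained = np.concatenate([lam / total_pos, np.zeros(k - k_eff)])
    return MDSResult(
        coordinates=pd.DataFrame(
            coords, index=dist.sample_ids, columns=[f"dim{i+1}" for i in range(k)]
        ),
        var_explained=var_explained,
        negative_eigenvalues_truncated=n_neg,
    )


def pearson_hclust(expr: ExprMatrix, axis: str = "samples"):
    """Average-linkage clustering on 1 - Pearson correlation.

    Returns ``(linkage_matrix, leaf_order)`` where ``leaf_order`` is a list
    of item labels in dendrogram order.
    """
    if axis == "samples":
        M = expr.values.to_numpy().T
        labels = list(expr.sample_ids)
    elif axis == "genes":
        M = expr.values.to_numpy()
        labels = list(expr.gene_ids)
    else:
        raise ValueError("axis must be 'samples' or 'genes'")
    if M.shape[0] < 2:
        raise ValueError("need at least two items to cluster")
    sd = M.std(axis=1)
    if (sd == 0).any():
        bad = [labels[i] for i in np.nonzero(sd == 0)[0][:5]]
        raise ValueError(f"zero-variance items cannot be correlated: {bad}")
    r = np.corrcoef(M)
    d = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    order = [labels[i] for i in hierarchy.leaves_list(Z)]
    return Z, order


def cv_compare(
    expr: ExprMatrix, samples: pd.DataFrame, group_by: str = "stock"
) -> CVReport:
    """Welch t-test over genes of within-group coefficients of variation."""
    groups = list(pd.unique(samples[group_by].astype(str)))
    if len(groups) != 2:
        raise ValueError(f"{group_by!r} must have exactly two levels, got {groups}")
    X = expr.values
    cvs = {}
    for g in groups:
        ids = samples.loc[samples[group_by].astype(str) == g, "sample_id"]
        if len(ids) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples")
        sub = X[ids]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cvs[g] = np.where(mean != 0, sd / mean, np.nan)
    cv_df = pd.DataFrame(cvs, index=expr.gene_ids)
    bad = ~np.isfinite(cv_df).all(axis=1)  # zero-mean genes: CV undefined
    dropped = int(bad.sum())
    cv_df = cv_df[~bad]
    res = stats.ttest_ind(cv_df[groups[0]], cv_df[groups[1]], equal_var=False)
    return CVReport(
        cv=cv_df, t=float(res.statistic), df=float(res.df), p=float(res.pvalue), dropped_genes=dropped
    )
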