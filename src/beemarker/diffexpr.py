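"""Precision-weighted gene-wise linear models with empirical-Bayes moderation.

The workflow mirrors the limma-voom approach to bulk RNA-seq differential
expression: log-CPM values are modelled gene-by-gene with a common design
matrix (treatment-coded, sucrose-only diet as the reference level, source
colony as a fixed-effect blocking factor); observation-level precision
weights come from a lowess fit of sqrt(residual SD) against average log
count; manual contrasts reparameterize the fits; residual variances are
shrunk toward a scaled inverse-chi-square prior estimated from all genes by
moment matching, giving moderated t-statistics with augmented degrees of
freedom; p-values are Benjamini-Hochberg adjusted and genes are called
differentially expressed at FDR < 0.05 and |log2 fold change| > 0.6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, ExprMatrix
from .setops import DEGSet

DEFAULT_FDR_MAX = 0.05
DEFAULT_LFC_MIN = 0.6

#: preferred reference levels for treatment coding
REFERENCES = {"diet": "sugar", "stock": "pol_line"}


class RankDeficientError(ValueError):
    """Design matrix is not full column rank; names the aliased columns."""


@dataclass
class DesignSpec:
    """Treatment-coded design matrix aligned with the sample table."""

    matrix: pd.DataFrame  # samples x columns
    factors: tuple[str, ...]
    reference_levels: dict[str, str]

    @property
    def columns(self) -> pd.Index:
        return self.matrix.columns

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix.to_numpy()))


@dataclass
class ContrastSpec:
    """A named linear combination of design columns."""

    name: str
    coefficients: Mapping[str, float] | Sequence[float]

    def vector(self, design_columns: pd.Index) -> np.ndarray:
        if isinstance(self.coefficients, Mapping):
            unknown = set(self.coefficients) - set(design_columns)
            if unknown:
                raise ValueError(f"contrast {self.name!r}: unknown columns {sorted(unknown)}")
            v = np.array([self.coefficients.get(c, 0.0) for c in design_columns])
        else:
            v = np.asarray(self.coefficients, dtype=float)
            if v.shape != (len(design_columns),):
                raise ValueError(
                    f"contrast {self.name!r}: length {v.size} != {len(design_columns)} columns"
                )
        if not np.any(v):
            raise ValueError(f"contrast {self.name!r} is the zero vector")
        return v


@dataclass
class GeneFits:
    """Vectorized per-gene least-squares fits (one row per gene).

    ``coef`` holds estimates (log2 scale), ``cov_unscaled`` the unscaled
    covariance of the estimates ((X' W X)^-1 or its contrast projection);
    multiply by sigma^2 for the sampling covariance.
    """

    gene_ids: pd.Index
    coef_names: list[str]
    coef: np.ndarray  # genes x k
    sigma: np.ndarray  # genes
    df_resid: np.ndarray  # genes
    cov_unscaled: np.ndarray  # genes x k x k

    def stdev_unscaled(self) -> np.ndarray:
        return np.sqrt(np.einsum("gkk->gk", self.cov_unscaled))


@dataclass
class ModerationPrior:
    """Scaled inverse-chi-square prior on residual variances."""

    d0: float  # prior degrees of freedom, may be +inf
    s0_sq: float  # prior variance


@dataclass
class VoomWeights:
    """Observation weights plus the fitted mean-variance trend."""

    weights: pd.DataFrame  # genes x samples
    trend_x: np.ndarray  # average log2 count at lowess knots
    trend_y: np.ndarray  # sqrt(residual SD) at knots


def build_design(samples: pd.DataFrame, formula_terms: Sequence[str]) -> DesignSpec:
    """Treatment-coded design with intercept; errors on rank deficiency."""
    cols = {"Intercept": np.ones(len(samples))}
    refs: dict[str, str] = {}
    for term in formula_terms:
        if term not in samples.columns:
            raise ValueError(f"term {term!r} not in sample table")
        levels = list(pd.unique(samples[term].astype(str)))
        if len(levels) < 2:
            raise ValueError(
                f"factor {term!r} is constant (single level {levels[0]!r}); "
                "it cannot enter the design"
            )
        ref = REFERENCES.get(term)
        if ref not in levels:
            ref = sorted(levels)[0]
        refs[term] = ref
        for lv in levels:
            if lv == ref:
                continue
            cols[f"{term}[{lv}]"] = (samples[term].astype(str) == lv).astype(float).to_numpy()
    X = pd.DataFrame(cols, index=samples.index)
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        # QR with pivoting: columns pivoted beyond the rank are aliased
        from scipy.linalg import qr

        _, _, piv = qr(arr, pivoting=True)
        aliased = [X.columns[i] for i in sorted(piv[rank:])]
        raise RankDeficientError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); aliased columns: {aliased}"
        )
    return DesignSpec(matrix=X, factors=tuple(formula_terms), reference_levels=refs)


def log_cpm(counts: CountMatrix) -> ExprMatrix:
    """log2 counts-per-million with the voom offsets: (K+0.5)/(L+1) * 1e6."""
    K = counts.counts.to_numpy(dtype=float)
    L = K.sum(axis=0)
    if (L <= 0).any():
        raise ValueError("library sizes must be positive")
    values = np.log2((K + 0.5) / (L + 1.0)[None, :] * 1e6)
    return ExprMatrix(
        pd.DataFrame(values, index=counts.gene_ids, columns=counts.sample_ids),
        transform_tag="logcpm",
    )


def _ols_fit(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Shared-design OLS for all genes: returns (beta G x P, resid G x N, df)."""
    pinv = np.linalg.pinv(X)
    beta = Y @ pinv.T
    resid = Y - beta @ X.T
    df = Y.shape[1] - np.linalg.matrix_rank(X)
    return beta, resid, df


def voom_weights(
    counts: CountMatrix, design: DesignSpec, span: float = 0.5
) -> VoomWeights:
    """Precision weights from the lowess sqrt-SD vs average log-count trend.

    Weight = (interpolated trend at the observation's fitted log2 count)^-4,
    with flat extrapolation beyond the trend's range.
    """
    if counts.n_genes < 10:
        raise ValueError("voom trend needs at least 10 genes")
    X = design.matrix.to_numpy()
    df_resid = counts.n_samples - np.linalg.matrix_rank(X)
    if df_resid < 2:
        raise ValueError("need >= 2 residual degrees of freedom for the voom trend")
    logcpm = log_cpm(counts)
    Y = logcpm.values.to_numpy()
    K = counts.counts.to_numpy(dtype=float)
    L = K.sum(axis=0)

    beta, resid, df = _ols_fit(Y, X)
    sigma = np.sqrt((resid**2).sum(axis=1) / df)
    sqrt_sd = np.sqrt(sigma)

    geo_mean_L = np.exp(np.mean(np.log(L + 1.0))) - 1.0
    sx = Y.mean(axis=1) + np.log2(geo_mean_L + 1.0) - np.log2(1e6)
    sy = sqrt_sd
    smoothed = sm_lowess(sy, sx, frac=span, it=3, delta=0.0, return_sorted=True)
    tx, ty = smoothed[:, 0], smoothed[:, 1]
    # collapse duplicate x for interpolation
    ux, inv = np.unique(tx, return_inverse=True)
    uy = np.zeros_like(ux)
    np.add.at(uy, inv, ty)
    uy /= np.bincount(inv)

    fitted = beta @ X.T  # fitted log-cpm, genes x samples
    fitted_logcount = fitted + (np.log2(L + 1.0) - np.log2(1e6))[None, :]
    pred_sqrt_sd = np.interp(fitted_logcount, ux, uy)  # flat extrapolation
    pred_sqrt_sd = np.maximum(pred_sqrt_sd, 1e-6)
    w = pred_sqrt_sd**-4.0
    if not np.all(np.isfinite(w)) or (w <= 0).any():
        raise ValueError("voom produced non-finite or non-positive weights")
    return VoomWeights(
        weights=pd.DataFrame(w, index=counts.gene_ids, columns=counts.sample_ids),
        trend_x=ux,
        trend_y=uy,
    )


def fit_gene_lms(
    y: ExprMatrix, design: DesignSpec, weights: pd.DataFrame | np.ndarray | None = None
) -> GeneFits:
    """Per-gene weighted least squares with a shared design matrix."""
    X = design.matrix.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficientError("design is rank deficient")
    Y = y.values.to_numpy(dtype=float)
    G, N = Y.shape
    P = X.shape[1]
    if weights is None:
        W = np.ones((G, N))
    else:
        W = weights.to_numpy() if isinstance(weights, pd.DataFrame) else np.asarray(weights, float)
        if W.shape != (G, N):
            raise ValueError(f"weights shape {W.shape} != {(G, N)}")
        if not np.all(np.isfinite(W)) or (W <= 0).any():
            raise ValueError("weights must be finite and positive")
    df = N - P
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    XtWX = np.einsum("gn,np,nq->gpq", W, X, X, optimize=True)
    XtWy = np.einsum("gn,np,gn->gp", W, X, Y, optimize=True)
    beta = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]
    resid = Y - beta @ X.T
    rss = np.einsum("gn,gn->g", W, resid**2)
    sigma = np.sqrt(np.maximum(rss, 0.0) / df)
    cov_unscaled = np.linalg.inv(XtWX)
    return GeneFits(
        gene_ids=y.gene_ids,
        coef_names=list(design.columns),
        coef=beta,
        sigma=sigma,
        df_resid=np.full(G, float(df)),
        cov_unscaled=cov_unscaled,
    )


def apply_contrasts(fits: GeneFits, contrasts: Sequence[ContrastSpec]) -> GeneFits:
    """Reparameterize fits to the given contrasts (c'beta, c'Vc)."""
    cols = pd.Index(fits.coef_names)
    C = np.column_stack([c.vector(cols) for c in contrasts])  # P x K
    coef = fits.coef @ C
    cov = np.einsum("pk,gpq,ql->gkl", C, fits.cov_unscaled, C, optimize=True)
    return GeneFits(
        gene_ids=fits.gene_ids,
        coef_names=[c.name for c in contrasts],
        coef=coef,
        sigma=fits.sigma,
        df_resid=fits.df_resid,
        cov_unscaled=cov,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) / x < 1e-8:
            break
    return x


def estimate_prior(
    sigma_sq: np.ndarray, df: np.ndarray, force_d0: float | None = None
) -> ModerationPrior:
    """Moment-matching estimate of the variance prior (d0, s0^2).

    ``e_g = log s_g^2 - digamma(d_g/2) + log(d_g/2)`` has mean
    ``log s0^2 + digamma(d0/2) - log(d0/2)`` and excess variance
    ``trigamma(d0/2)`` under the scaled inverse-chi-square model; the excess
    over the sampling component ``trigamma(d_g/2)`` identifies d0.
    """
    ok = sigma_sq > 0
    if not ok.any():
        raise ValueError("all residual variances are zero; data are degenerate")
    s2, d = sigma_sq[ok], df[ok]
    e = np.log(s2) - digamma(d / 2.0) + np.log(d / 2.0)
    if force_d0 is not None:
        d0 = force_d0
    else:
        excess = float(np.var(e, ddof=1) - np.mean(polygamma(1, d / 2.0)))
        d0 = 2.0 * _trigamma_inverse(excess) if excess > 0 else math.inf
    if math.isinf(d0):
        s0_sq = float(np.exp(np.mean(e)))
    else:
        s0_sq = float(np.exp(np.mean(e) + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return ModerationPrior(d0=d0, s0_sq=s0_sq)


def ebayes_moderate(
    fits: GeneFits, force_d0: float | None = None
) -> tuple[ModerationPrior, dict[str, pd.DataFrame]]:
    """Moderated t-tests for every coefficient of ``fits``.

    Returns the estimated prior and one result table per coefficient with
    columns gene_id, logFC, t, p, fdr, direction. ``force_d0`` overrides the
    prior degrees of freedom (0 recovers ordinary t-tests; ``math.inf``
    fully pools variances).
    """
    if len(fits.gene_ids) < 10:
        raise ValueError("need >= 10 genes to estimate the variance prior")
    sigma_sq = fits.sigma**2
    if force_d0 == 0:
        prior = ModerationPrior(d0=0.0, s0_sq=float(np.mean(sigma_sq[sigma_sq > 0])))
        post_var = sigma_sq
        df_total = fits.df_resid
    else:
        prior = estimate_prior(sigma_sq, fits.df_resid, force_d0=force_d0)
        if math.isinf(prior.d0):
            post_var = np.full_like(sigma_sq, prior.s0_sq)
            df_total = np.full_like(fits.df_resid, np.inf)
        else:
            post_var = (prior.d0 * prior.s0_sq + fits.df_resid * sigma_sq) / (
                prior.d0 + fits.df_resid
            )
            df_total = prior.d0 + fits.df_resid
    stdev_unscaled = fits.stdev_unscaled()
    results: dict[str, pd.DataFrame] = {}
    for k, name in enumerate(fits.coef_names):
        se = np.sqrt(post_var) * stdev_unscaled[:, k]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, fits.coef[:, k] / se, 0.0)
        finite_df = np.where(np.isinf(df_total), 1e12, df_total)
        p = 2.0 * stats.t.sf(np.abs(t), finite_df)
        results[name] = pd.DataFrame(
            {
                "gene_id": fits.gene_ids,
                "logFC": fits.coef[:, k],
                "t": t,
                "p": p,
                "fdr": bh_adjust(p),
                "direction": np.sign(fits.coef[:, k]).astype(int),
            }
        ).set_index("gene_id")
    return prior, results


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise ValueError("p-values contain NaN")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    result: pd.DataFrame,
    name: str = "degs",
    fdr_max: float = DEFAULT_FDR_MAX,
    lfc_min: float = DEFAULT_LFC_MIN,
) -> DEGSet:
    """Strict-threshold DEG call: fdr < fdr_max and |logFC| > lfc_min."""
    if fdr_max <= 0 or lfc_min < 0:
        raise ValueError("thresholds must be positive")
    hit = (result["fdr"] < fdr_max) & (result["logFC"].abs() > lfc_min)
    genes = result.index[hit]
    directions = {g: int(np.sign(result.loc[g, "logFC"])) for g in genes}
    return DEGSet(name=name, genes=set(genes), directions=directions)


def voom_pipeline(
    counts: CountMatrix,
    samples: pd.DataFrame,
    formula_terms: Sequence[str],
    contrasts: Sequence[ContrastSpec] | None = None,
    force_d0: float | None = None,
) -> tuple[ModerationPrior, dict[str, pd.DataFrame]]:
    """Counts to moderated-t tables: design, voom weights, WLS, contrasts, eBayes."""
    design = build_design(samples, formula_terms)
    vw = voom_weights(counts, design)
    fits = fit_gene_lms(log_cpm(counts), design, vw.weights)
    if contrasts:
        fits = apply_contrasts(fits, list(contrasts))
    return ebayes_moderate(fits, force_d0=force_d0)
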