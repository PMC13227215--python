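"""Low-count filtering, size-factor normalization and the parametric VST.

Genes with fewer than 50 reads summed over all libraries are removed before
any statistics. Normalization is median-of-ratios: each sample's factor is
the median, over genes positive in every sample, of the ratio of its count
to the gene's geometric mean, rescaled so the factors have geometric mean 1.
The variance stabilizing transformation is the closed form for an NB model
with dispersion trend alpha(mu) = a0 + a1/mu:

    vst(u) = log2( (1 + a1 + 2 a0 u + 2 sqrt(a0 u (1 + a1 + a0 u))) / (4 a0) )

with u the normalized count. It is strictly increasing in u, finite at
u = 0, and behaves like log2(u) for large u.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import CountMatrix, DispersionTrend, ExprMatrix, SizeFactors

logger = logging.getLogger(__name__)

DEFAULT_MIN_TOTAL = 50


def filter_low_counts(counts: CountMatrix, min_total: int = DEFAULT_MIN_TOTAL) -> CountMatrix:
    """Keep genes whose total count across all libraries is >= ``min_total``."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = counts.counts.sum(axis=1) >= min_total
    if not keep.any():
        logger.warning("low-count filter removed every gene (min_total=%d)", min_total)
    return CountMatrix(counts.counts.loc[keep], counts.biotype.loc[keep])


def estimate_size_factors(counts: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors over genes positive in every sample."""
    arr = counts.counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "use a pseudo-reference fallback or filter samples"
        )
    ref = arr[positive]
    log_geomean = np.mean(np.log(ref), axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    log_s = np.median(ratios, axis=0)
    log_s = log_s - log_s.mean()  # geometric mean 1
    return SizeFactors(pd.Series(np.exp(log_s), index=counts.sample_ids))


def fit_dispersion_trend(counts: CountMatrix, s: SizeFactors) -> DispersionTrend:
    """Fit alpha(mu) = a0 + a1/mu to gene-wise method-of-moments dispersions.

    Dispersions are computed on size-factor-normalized counts,
    ``alpha_g = max(0, (var_g - mean_g) / mean_g^2)``; genes with zero
    dispersion or non-positive mean are excluded. The linear fit in 1/mu is
    an iteratively reweighted least squares with gamma-style weights
    (1/fitted^2) and exclusion of extreme-ratio genes, so single outlying
    genes do not drive the trend.
    """
    norm = counts.counts.to_numpy(dtype=float) / s.s.to_numpy()[None, :]
    mu = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1)
    ok = mu > 0
    if ok.sum() < 50:
        raise ValueError("need >= 50 genes with positive normalized mean")
    alpha_hat = np.zeros_like(mu)
    alpha_hat[ok] = np.maximum(0.0, (var[ok] - mu[ok]) / mu[ok] ** 2)
    use = ok & (alpha_hat > 0)
    if use.sum() < 10:
        logger.warning("dispersion trend: only %d usable genes", use.sum())
    x = 1.0 / mu[use]
    y = alpha_hat[use]
    X = np.column_stack([np.ones_like(x), x])
    w = np.ones_like(y)
    coef = np.array([np.median(y), 0.0])
    active = np.ones_like(y, dtype=bool)
    for _ in range(10):
        Xa, ya, wa = X[active], y[active], w[active]
        WX = Xa * wa[:, None]
        coef_new, *_ = np.linalg.lstsq(WX.T @ Xa, WX.T @ ya, rcond=None)
        fitted = np.maximum(X @ coef_new, 1e-12)
        ratio = y / fitted
        active = (ratio < 15.0) & (ratio > 1e-4)
        if not active.any():
            active[:] = True
        w = 1.0 / fitted**2
        if np.allclose(coef_new, coef, rtol=1e-8, atol=1e-12):
            coef = coef_new
            break
        coef = coef_new
    a0, a1 = float(coef[0]), float(coef[1])
    if a0 <= 0:
        logger.warning("dispersion trend a0=%g <= 0; clamping to 1e-8", a0)
        a0 = 1e-8
    a1 = max(a1, 0.0)
    return DispersionTrend(a0=a0, a1=a1)


def vst_values(u: np.ndarray, trend: DispersionTrend) -> np.ndarray:
    """Closed-form VST of normalized counts ``u`` under ``trend``."""
    u = np.asarray(u, dtype=float)
    a0, a1 = trend.a0, trend.a1
    inner = 1.0 + a1 + 2.0 * a0 * u + 2.0 * np.sqrt(a0 * u * (1.0 + a1 + a0 * u))
    return np.log2(inner / (4.0 * a0))


def vst_transform(
    counts: CountMatrix, s: SizeFactors, trend: DispersionTrend
) -> ExprMatrix:
    norm = counts.counts.to_numpy(dtype=float) / s.s.to_numpy()[None, :]
    values = vst_values(norm, trend)
    return ExprMatrix(
        pd.DataFrame(values, index=counts.gene_ids, columns=counts.sample_ids),
        transform_tag="vst",
    )


def vst_pipeline(
    counts: CountMatrix, min_total: int = DEFAULT_MIN_TOTAL
) -> tuple[CountMatrix, SizeFactors, DispersionTrend, ExprMatrix]:
    """Filter, normalize, fit the trend and transform in one call."""
    filtered = filter_low_counts(counts, min_total)
    s = estimate_size_factors(filtered)
    trend = fit_dispersion_trend(filtered, s)
    return filtered, s, trend, vst_transform(filtered, s, trend)
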