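"""Design coding, voom weights, weighted fits, moderation and DEG calling."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import beemarker as bm
from beemarker.diffexpr import RankDeficientError, estimate_prior

from conftest import null_config


def _samples(n_per, diets=("sugar", "pollen", "chlorella", "spirulina"), colonies=("c1",)):
    rows = []
    for d in diets:
        for c in colonies:
            for i in range(n_per):
                rows.append({"sample_id": f"{d}.{c}.{i}", "stock": "pol_line", "diet": d, "colony": c})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- build_design

def test_four_level_diet_design_has_intercept_plus_three_columns():
    design = bm.build_design(_samples(2), ["diet"])
    assert design.matrix.shape == (8, 4)
    assert design.reference_levels["diet"] == "sugar"
    assert "diet[sugar]" not in design.columns


def test_constant_blocking_factor_is_rejected():
    with pytest.raises(ValueError, match="colony"):
        bm.build_design(_samples(2, colonies=("only",)), ["diet", "colony"])


def test_colony_nested_in_stock_names_aliased_columns():
    rows = []
    for stock, cols in [("pol_line", ["p1", "p2"]), ("russian", ["r1", "r2"])]:
        for c in cols:
            for d in ("sugar", "pollen"):
                rows.append({"sample_id": f"{stock}.{c}.{d}", "stock": stock, "diet": d, "colony": c})
    samples = pd.DataFrame(rows)
    with pytest.raises(RankDeficientError, match="aliased"):
        bm.build_design(samples, ["stock", "diet", "colony"])


def test_balanced_design_rank_matches_numeric_oracle():
    rows = []
    for stock in ("pol_line", "russian"):
        for d in ("sugar", "pollen", "chlorella", "spirulina"):
            for c in ("c1", "c2", "c3"):
                rows.append({"sample_id": f"{stock}.{d}.{c}", "stock": stock, "diet": d, "colony": f"{stock}.{c}"})
    samples = pd.DataFrame(rows)
    design = bm.build_design(samples, ["diet", "colony"])
    assert design.rank == np.linalg.matrix_rank(design.matrix.to_numpy())
    assert design.rank == design.matrix.shape[1]


# -------------------------------------------------------------------- log_cpm

def test_log_cpm_closed_form_zero_count():
    counts = pd.DataFrame({"s1": [0, 999_999]}, index=["g0", "gbig"])
    cm = bm.CountMatrix(counts, pd.Series("other", index=counts.index))
    lc = bm.log_cpm(cm)
    assert lc.values.loc["g0", "s1"] == pytest.approx(-1.0, abs=1e-12)


def test_log_cpm_depth_invariance_and_formula_oracle():
    rng = np.random.default_rng(2)
    counts = pd.DataFrame(
        rng.integers(50, 5000, size=(20, 4)), index=[f"g{i}" for i in range(20)]
    )
    cm = bm.CountMatrix(counts, pd.Series("other", index=counts.index))
    lc = bm.log_cpm(cm).values.to_numpy()
    K = counts.to_numpy(float)
    L = K.sum(axis=0)
    oracle = np.log2((K + 0.5) / (L + 1) * 1e6)
    assert np.allclose(lc, oracle, atol=1e-12)
    doubled = bm.CountMatrix(counts.assign(s_dup=counts.iloc[:, 0] * 2), pd.Series("other", index=counts.index))
    lc2 = bm.log_cpm(doubled).values
    assert np.abs(lc2["s_dup"].to_numpy() - lc[:, 0]).max() < 1e-3


# --------------------------------------------------------------- voom_weights

def _counts_with_sd_profile(n_genes, n_samples, sd_fn, seed=0):
    """Counts whose log2 scale is mu_g + N(0, sd(mu_g)) — known voom trend."""
    rng = np.random.default_rng(seed)
    mu = rng.uniform(6, 13, size=n_genes)
    eps = rng.normal(0, 1, size=(n_genes, n_samples)) * sd_fn(mu)[:, None]
    counts = np.rint(2 ** (mu[:, None] + eps)).astype(np.int64)
    idx = [f"g{i}" for i in range(n_genes)]
    return bm.CountMatrix(
        pd.DataFrame(counts, index=idx, columns=[f"s{j}" for j in range(n_samples)]),
        pd.Series("other", index=idx),
    )


def test_homoskedastic_data_gives_flat_weights():
    cm = _counts_with_sd_profile(300, 12, lambda mu: np.full_like(mu, 0.3))
    design = bm.build_design(
        pd.DataFrame({"sample_id": cm.sample_ids, "stock": "x", "diet": "sugar", "colony": "c"}),
        [],
    )
    vw = bm.voom_weights(cm, design)
    w = vw.weights.to_numpy()
    assert w.max() / w.min() < 2.0


def test_decreasing_trend_gives_weights_increasing_with_count():
    cm = _counts_with_sd_profile(400, 12, lambda mu: 1.2 - 0.12 * (mu - 6), seed=3)
    design = bm.build_design(
        pd.DataFrame({"sample_id": cm.sample_ids, "stock": "x", "diet": "sugar", "colony": "c"}),
        [],
    )
    vw = bm.voom_weights(cm, design)
    w = vw.weights.to_numpy().ravel()
    fitted_count = np.log2(cm.counts.to_numpy() + 0.5).ravel()
    rho = stats.spearmanr(fitted_count, w).statistic
    assert rho > 0.9


def test_trend_interpolation_reproduces_knot_values():
    cm = _counts_with_sd_profile(100, 8, lambda mu: np.full_like(mu, 0.4), seed=5)
    design = bm.build_design(
        pd.DataFrame({"sample_id": cm.sample_ids, "stock": "x", "diet": "sugar", "colony": "c"}),
        [],
    )
    vw = bm.voom_weights(cm, design)
    interp = np.interp(vw.trend_x, vw.trend_x, vw.trend_y)
    assert np.allclose(interp, vw.trend_y, atol=1e-12)


# --------------------------------------------------------------- fit_gene_lms

def test_intercept_only_fit_recovers_mean_and_variance():
    rng = np.random.default_rng(8)
    Y = rng.normal(size=(30, 10))
    expr = bm.ExprMatrix(
        pd.DataFrame(Y, index=[f"g{i}" for i in range(30)], columns=[f"s{j}" for j in range(10)]),
        "logcpm",
    )
    design = bm.build_design(
        pd.DataFrame({"sample_id": expr.sample_ids, "stock": "x", "diet": "sugar", "colony": "c"}),
        [],
    )
    fits = bm.fit_gene_lms(expr, design)
    assert np.allclose(fits.coef[:, 0], Y.mean(axis=1), atol=1e-12)
    assert np.allclose(fits.sigma**2, Y.var(axis=1, ddof=1), atol=1e-12)


def test_weighted_fit_matches_normal_equations_oracle():
    rng = np.random.default_rng(9)
    n, p, g = 16, 4, 25
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    Y = rng.normal(size=(g, n))
    W = rng.uniform(0.2, 3.0, size=(g, n))
    design = bm.DesignSpec(
        matrix=pd.DataFrame(X, columns=[f"c{j}" for j in range(p)]),
        factors=(),
        reference_levels={},
    )
    expr = bm.ExprMatrix(
        pd.DataFrame(Y, index=[f"g{i}" for i in range(g)], columns=[f"s{j}" for j in range(n)]),
        "logcpm",
    )
    fits = bm.fit_gene_lms(expr, design, W)
    for i in range(g):  # explicit per-gene normal equations
        A = X.T @ np.diag(W[i]) @ X
        b = X.T @ np.diag(W[i]) @ Y[i]
        beta = np.linalg.solve(A, b)
        assert np.allclose(fits.coef[i], beta, atol=1e-10)
        resid = Y[i] - X @ beta
        sigma2 = (W[i] * resid**2).sum() / (n - p)
        assert fits.sigma[i] ** 2 == pytest.approx(sigma2, abs=1e-10)
        assert np.allclose(fits.cov_unscaled[i], np.linalg.inv(A), atol=1e-10)


def test_planted_coefficients_recovered_from_tiny_noise():
    rng = np.random.default_rng(10)
    n = 24
    X = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
    beta_true = np.array([[2.0, -1.5], [0.5, 3.0]])
    Y = beta_true @ X.T + rng.normal(0, 1e-5, size=(2, n))
    design = bm.DesignSpec(pd.DataFrame(X, columns=["a", "b"]), (), {})
    expr = bm.ExprMatrix(pd.DataFrame(Y, index=["g1", "g2"], columns=[f"s{j}" for j in range(n)]), "logcpm")
    fits = bm.fit_gene_lms(expr, design)
    assert np.allclose(fits.coef, beta_true, atol=1e-3)


# ------------------------------------------------------------ apply_contrasts

def test_unit_contrast_is_the_coefficient_itself():
    rng = np.random.default_rng(11)
    Y = rng.normal(size=(15, 12))
    X = np.column_stack([np.ones(12), rng.normal(size=(12, 2))])
    design = bm.DesignSpec(pd.DataFrame(X, columns=["i", "a", "b"]), (), {})
    expr = bm.ExprMatrix(pd.DataFrame(Y, index=[f"g{i}" for i in range(15)], columns=[f"s{j}" for j in range(12)]), "logcpm")
    fits = bm.fit_gene_lms(expr, design)
    cfits = bm.apply_contrasts(fits, [bm.ContrastSpec("a", {"a": 1.0})])
    assert np.allclose(cfits.coef[:, 0], fits.coef[:, 1], atol=1e-12)
    assert np.allclose(
        cfits.cov_unscaled[:, 0, 0], fits.cov_unscaled[:, 1, 1], atol=1e-12
    )


def test_group_difference_contrast_equals_difference_of_means():
    rng = np.random.default_rng(12)
    ga, gb = rng.normal(size=(5, 6)), rng.normal(size=(5, 6))
    Y = np.hstack([ga, gb])
    X = np.zeros((12, 2))
    X[:6, 0] = 1.0
    X[6:, 1] = 1.0
    design = bm.DesignSpec(pd.DataFrame(X, columns=["gA", "gB"]), (), {})
    expr = bm.ExprMatrix(pd.DataFrame(Y, index=[f"g{i}" for i in range(5)], columns=[f"s{j}" for j in range(12)]), "logcpm")
    fits = bm.fit_gene_lms(expr, design)
    cfits = bm.apply_contrasts(fits, [bm.ContrastSpec("A-B", {"gA": 1.0, "gB": -1.0})])
    assert np.allclose(cfits.coef[:, 0], ga.mean(axis=1) - gb.mean(axis=1), atol=1e-12)


def test_contrast_variance_matches_quadratic_form_oracle():
    rng = np.random.default_rng(13)
    A = rng.normal(size=(3, 3))
    V = A @ A.T
    fits = bm.GeneFits(
        gene_ids=pd.Index(["g"]),
        coef_names=["a", "b", "c"],
        coef=np.array([[1.0, 2.0, 3.0]]),
        sigma=np.array([1.0]),
        df_resid=np.array([5.0]),
        cov_unscaled=V[None, :, :],
    )
    c = np.array([1.0, -2.0, 0.5])
    out = bm.apply_contrasts(fits, [bm.ContrastSpec("c", c)])
    assert out.cov_unscaled[0, 0, 0] == pytest.approx(c @ V @ c, abs=1e-12)


def test_zero_contrast_rejected():
    with pytest.raises(ValueError, match="zero"):
        bm.ContrastSpec("z", [0.0, 0.0]).vector(pd.Index(["a", "b"]))


# ------------------------------------------------------------ ebayes_moderate

def _toy_fits(sigma, df=6.0, coef=None, g=None):
    g = g or len(sigma)
    return bm.GeneFits(
        gene_ids=pd.Index([f"g{i}" for i in range(g)]),
        coef_names=["eff"],
        coef=np.asarray(coef if coef is not None else np.ones((g, 1))),
        sigma=np.asarray(sigma, float),
        df_resid=np.full(g, float(df)),
        cov_unscaled=np.tile(np.array([[[0.25]]]), (g, 1, 1)),
    )


def test_equal_variances_drive_prior_df_to_infinity():
    fits = _toy_fits(np.full(50, 1.3))
    prior, results = bm.ebayes_moderate(fits)
    assert math.isinf(prior.d0)
    # all posterior variances equal the prior -> z-like statistic
    t = results["eff"]["t"]
    assert np.allclose(t, t.iloc[0])


def test_forcing_d0_zero_recovers_ordinary_t():
    rng = np.random.default_rng(14)
    sigma = rng.uniform(0.5, 2.0, 40)
    coef = rng.normal(size=(40, 1))
    fits = _toy_fits(sigma, coef=coef)
    _, results = bm.ebayes_moderate(fits, force_d0=0)
    expected_t = coef[:, 0] / (sigma * 0.5)
    assert np.allclose(results["eff"]["t"], expected_t, atol=1e-10)
    expected_p = 2 * stats.t.sf(np.abs(expected_t), 6)
    assert np.allclose(results["eff"]["p"], expected_p, atol=1e-12)


def test_prior_parameters_recovered_within_25_percent():
    rng = np.random.default_rng(42)
    G, d, d0, s0sq = 5000, 10, 6.0, 0.8
    sigma2 = s0sq * d0 / rng.chisquare(d0, G)
    s2 = sigma2 * rng.chisquare(d, G) / d
    prior = estimate_prior(s2, np.full(G, float(d)))
    assert prior.d0 == pytest.approx(d0, rel=0.25)
    assert prior.s0_sq == pytest.approx(s0sq, rel=0.25)


def test_null_simulation_p_values_are_uniform():
    ds = bm.simulate_experiment(null_config(seed=17))
    f = bm.filter_low_counts(ds.counts)
    _, results = bm.voom_pipeline(f, ds.samples, ["diet", "colony"])
    p = results["diet[pollen]"]["p"]
    assert stats.kstest(p, "uniform").statistic < 0.05


def test_blocking_on_colony_improves_null_calibration():
    cfg = null_config(seed=19)
    cfg.n_colonies_per_stock = 3
    cfg.cages_per_colony_per_diet = 1
    cfg.colony_sd = 0.8  # strong colony offsets
    ds = bm.simulate_experiment(cfg)
    f = bm.filter_low_counts(ds.counts)
    _, with_block = bm.voom_pipeline(f, ds.samples, ["diet", "colony"])
    _, without = bm.voom_pipeline(f, ds.samples, ["diet"])
    ks_with = stats.kstest(with_block["diet[pollen]"]["p"], "uniform").statistic
    ks_without = stats.kstest(without["diet[pollen]"]["p"], "uniform").statistic
    assert ks_with < ks_without


def test_contrast_coherence_between_reference_codings(small_dataset):
    """(A vs sugar) - (B vs sugar) equals the direct A-vs-B contrast."""
    ds = small_dataset
    sub = ds.samples[ds.samples.stock == "pol_line"].reset_index(drop=True)
    f = bm.filter_low_counts(
        bm.CountMatrix(ds.counts.counts[sub.sample_id], ds.counts.biotype)
    )
    design = bm.build_design(sub, ["diet", "colony"])
    vw = bm.voom_weights(f, design)
    fits = bm.fit_gene_lms(bm.log_cpm(f), design, vw.weights)
    cf = bm.apply_contrasts(
        fits,
        [
            bm.ContrastSpec("pollen", {"diet[pollen]": 1.0}),
            bm.ContrastSpec("spirulina", {"diet[spirulina]": 1.0}),
            bm.ContrastSpec("spi-pol", {"diet[spirulina]": 1.0, "diet[pollen]": -1.0}),
        ],
    )
    diff = cf.coef[:, 1] - cf.coef[:, 0]
    assert np.allclose(diff, cf.coef[:, 2], atol=1e-10)


# ------------------------------------------------------- bh_adjust / call_degs

def test_bh_hand_computation():
    assert np.allclose(bm.bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])


def test_bh_ties_and_identity():
    assert np.allclose(bm.bh_adjust(np.array([0.2, 0.2, 0.2])), 0.2)
    assert bm.bh_adjust(np.array([0.42]))[0] == pytest.approx(0.42)


def test_bh_rejects_nan():
    with pytest.raises(ValueError):
        bm.bh_adjust(np.array([0.1, np.nan]))


def test_deg_thresholds_are_strict():
    table = pd.DataFrame(
        {
            "logFC": [1.0, 0.6, 0.61, -0.7],
            "fdr": [0.05, 0.01, 0.01, 0.049],
            "t": 0.0,
            "p": 0.0,
        },
        index=["fdr_at_cut", "lfc_at_cut", "hit_up", "hit_down"],
    )
    degs = bm.call_degs(table)
    assert degs.genes == {"hit_up", "hit_down"}
    assert degs.directions == {"hit_up": 1, "hit_down": -1}


def test_deg_calls_match_brute_force_filter():
    rng = np.random.default_rng(20)
    table = pd.DataFrame(
        {
            "logFC": rng.normal(0, 1, 500),
            "fdr": rng.uniform(0, 1, 500),
            "t": 0.0,
            "p": 0.0,
        },
        index=[f"g{i}" for i in range(500)],
    )
    degs = bm.call_degs(table)
    expected = {
        g
        for g in table.index
        if table.loc[g, "fdr"] < 0.05 and abs(table.loc[g, "logFC"]) > 0.6
    }
    assert degs.genes == expected
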