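"""Random-forest regression of cage dry mass with recursive feature elimination.

A random forest predicts the per-cage mean head+thorax dry mass (mg) from
transcript abundance (VST values). Model quality is judged entirely
out-of-bag (OOB): every sample's prediction is averaged over the trees that
did not see it. The elimination loop tunes ``mtry`` over a small grid by
OOB RMSE, scores features by OOB permutation importance (mean increase in
OOB MSE when the feature is permuted), drops every feature whose importance
is non-positive, and repeats until no feature drops; the optimal round
minimizes OOB RMSE, ties resolved toward the smaller feature set. Selected
features are then triaged by their Pearson correlation with weight and a
panel is cut at r >= 0.75 (inclusive) with p < 0.05.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .containers import ExprMatrix

logger = logging.getLogger(__name__)

_MAX_TILED_ROWS = 200_000  # memory cap for block-permutation prediction


@dataclass
class RFConfig:
    n_trees: int = 1000
    mtry_grid: tuple[int, ...] | None = None  # None -> {p/10, p/3, p/2, sqrt(p)}
    min_node_size: int = 5
    importance_mode: str = "permutation_oob"  # or "impurity_corrected"
    seed: int = 0

    def grid_for(self, p: int) -> list[int]:
        if self.mtry_grid is not None:
            vals = [min(int(m), p) for m in self.mtry_grid]
        else:
            vals = [p // 10, p // 3, p // 2, round(math.sqrt(p))]
        return sorted({max(1, v) for v in vals})


@dataclass
class RFFit:
    model: RandomForestRegressor
    feature_ids: list[str]
    oob_pred: np.ndarray
    oob_rmse: float
    oob_r2: float
    importances: pd.Series | None


@dataclass
class RFERound:
    n_features: int
    feature_ids: list[str]
    mtry: int
    oob_rmse: float
    oob_r2: float


@dataclass
class RFETrace:
    rounds: list[RFERound]
    optimum_round: int

    @property
    def optimum_features(self) -> list[str]:
        return self.rounds[self.optimum_round].feature_ids


def _fit_seed(seed: int, round_i: int, mtry: int) -> int:
    return (seed * 1_000_003 + round_i * 10_007 + mtry * 101 + 7) % (2**31)


def _oob_indices(model: RandomForestRegressor, n: int) -> list[np.ndarray]:
    out = []
    for sampled in model.estimators_samples_:
        mask = np.ones(n, dtype=bool)
        mask[sampled] = False
        out.append(np.nonzero(mask)[0])
    return out


def _oob_predictions(
    model: RandomForestRegressor, X: np.ndarray, oob_idx: list[np.ndarray]
) -> np.ndarray:
    n = X.shape[0]
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    pred_sum = np.zeros(n)
    pred_count = np.zeros(n)
    for tree, oob in zip(model.estimators_, oob_idx):
        if oob.size == 0:
            continue
        pred_sum[oob] += tree.predict(np.ascontiguousarray(X32[oob]), check_input=False)
        pred_count[oob] += 1
    if (pred_count == 0).any():
        raise ValueError(
            "some samples were never out-of-bag; increase n_trees (>= 100 recommended)"
        )
    return pred_sum / pred_count


def _permutation_oob_importance(
    model: RandomForestRegressor,
    X: np.ndarray,
    y: np.ndarray,
    oob_idx: list[np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """Mean over trees of the OOB MSE increase when one feature is permuted.

    Permuted predictions are computed in feature blocks: the OOB rows are
    tiled once per feature in the block with only that feature's column
    shuffled, so each tree needs only a few ``predict`` calls.
    """
    n, p = X.shape
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    imp = np.zeros(p)
    for tree, oob in zip(model.estimators_, oob_idx):
        if oob.size == 0:
            continue
        Xo = np.ascontiguousarray(X32[oob])
        yo = y[oob]
        base_mse = np.mean((tree.predict(Xo, check_input=False) - yo) ** 2)
        chunk = max(1, _MAX_TILED_ROWS // max(1, oob.size))
        for start in range(0, p, chunk):
            feats = range(start, min(start + chunk, p))
            k = len(feats)
            tiled = np.tile(Xo, (k, 1))
            for bi, j in enumerate(feats):
                perm = rng.permutation(oob.size)
                tiled[bi * oob.size : (bi + 1) * oob.size, j] = Xo[perm, j]
            preds = tree.predict(tiled, check_input=False).reshape(k, oob.size)
            imp[start : start + k] += np.mean((preds - yo) ** 2, axis=1) - base_mse
    return imp / len(model.estimators_)


def rf_oob_fit(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    config: RFConfig,
    mtry: int | None = None,
    compute_importance: bool = True,
    _round: int = 0,
) -> RFFit:
    """Fit one forest and evaluate it strictly out-of-bag.

    ``X`` is samples x features. OOB R^2 is 1 - SSE/SST of the OOB
    predictions; importances follow ``config.importance_mode``
    ("permutation_oob" gives signed scores; "impurity_corrected" subtracts
    the impurity importance of a forest refit on permuted responses).
    """
    if X.shape[0] < 10:
        raise ValueError("need at least 10 samples")
    arr = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    if not (np.isfinite(arr).all() and np.isfinite(yv).all()):
        raise ValueError("missing or non-finite values in predictors or response")
    p = arr.shape[1]
    if mtry is None:
        mtry = max(1, round(math.sqrt(p)))
    seed = _fit_seed(config.seed, _round, mtry)
    model = RandomForestRegressor(
        n_estimators=config.n_trees,
        max_features=min(mtry, p),
        min_samples_leaf=config.min_node_size,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    model.fit(arr, yv)
    oob_idx = _oob_indices(model, arr.shape[0])
    oob_pred = _oob_predictions(model, arr, oob_idx)
    sse = float(np.sum((oob_pred - yv) ** 2))
    sst = float(np.sum((yv - yv.mean()) ** 2))
    oob_rmse = math.sqrt(sse / len(yv))
    oob_r2 = 1.0 - sse / sst if sst > 0 else -math.inf
    importances = None
    if compute_importance:
        if config.importance_mode == "permutation_oob":
            rng = np.random.default_rng(seed + 1)
            imp = _permutation_oob_importance(model, arr, yv, oob_idx, rng)
        elif config.importance_mode == "impurity_corrected":
            null_model = RandomForestRegressor(
                n_estimators=config.n_trees,
                max_features=min(mtry, p),
                min_samples_leaf=config.min_node_size,
                bootstrap=True,
                random_state=seed + 2,
                n_jobs=1,
            )
            rng = np.random.default_rng(seed + 3)
            null_model.fit(arr, rng.permutation(yv))
            imp = model.feature_importances_ - null_model.feature_importances_
        else:
            raise ValueError(f"unknown importance_mode {config.importance_mode!r}")
        importances = pd.Series(imp, index=X.columns)
    return RFFit(
        model=model,
        feature_ids=list(X.columns),
        oob_pred=oob_pred,
        oob_rmse=oob_rmse,
        oob_r2=oob_r2,
        importances=importances,
    )


def rfe_select(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    config: RFConfig,
    max_rounds: int = 50,
) -> RFETrace:
    """Recursive elimination of non-positive-importance features.

    Each round tunes mtry by OOB RMSE, records (feature set, OOB RMSE, OOB
    R^2) for the tuned model, then drops every feature with importance <= 0.
    Stops when nothing drops, fewer than two features remain, or the round
    limit is reached. The optimum round minimizes OOB RMSE (ties: smaller
    feature set).
    """
    if X.shape[1] < 2:
        raise ValueError("need at least two features to eliminate")
    features = list(X.columns)
    rounds: list[RFERound] = []
    for round_i in range(max_rounds):
        sub = X[features]
        best: RFFit | None = None
        best_mtry = None
        for mtry in config.grid_for(len(features)):
            fit = rf_oob_fit(sub, y, config, mtry=mtry, compute_importance=False, _round=round_i)
            if best is None or fit.oob_rmse < best.oob_rmse:
                best, best_mtry = fit, mtry
        assert best is not None and best_mtry is not None
        best = rf_oob_fit(sub, y, config, mtry=best_mtry, compute_importance=True, _round=round_i)
        rounds.append(
            RFERound(
                n_features=len(features),
                feature_ids=list(features),
                mtry=best_mtry,
                oob_rmse=best.oob_rmse,
                oob_r2=best.oob_r2,
            )
        )
        assert best.importances is not None
        keep = [f for f in features if best.importances[f] > 0]
        if len(keep) == len(features):
            break
        if len(keep) < 2:
            break
        features = keep
    optimum = 0
    for i, rd in enumerate(rounds):
        if rd.oob_rmse < rounds[optimum].oob_rmse or (
            rd.oob_rmse == rounds[optimum].oob_rmse
            and rd.n_features < rounds[optimum].n_features
        ):
            optimum = i
    return RFETrace(rounds=rounds, optimum_round=optimum)


def weight_correlations(
    expr: ExprMatrix, y: np.ndarray | pd.Series, feature_ids: Sequence[str]
) -> pd.DataFrame:
    """Per-feature Pearson r with weight and two-sided t-distribution p.

    Returns a table sorted by descending r with columns r, p, defined
    (False for zero-variance features, whose r is NaN).
    """
    missing = set(feature_ids) - set(expr.gene_ids)
    if missing:
        raise ValueError(f"features not in expression matrix: {sorted(missing)[:5]}")
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    sub = expr.values.loc[list(feature_ids)].to_numpy()
    xc = sub - sub.mean(axis=1, keepdims=True)
    yc = yv - yv.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = math.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(sx > 0, (xc @ yc) / (sx * sy), np.nan)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))  # +-inf at |r| = 1 -> p = 0
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    out = pd.DataFrame(
        {"r": r, "p": p, "defined": ~np.isnan(r)}, index=pd.Index(feature_ids, name="gene_id")
    )
    return out.sort_values("r", ascending=False, na_position="last")


@dataclass
class PanelSelection:
    panel: set[str]  # r >= r_cut, p < alpha
    positive_significant: set[str]  # r > 0, p < alpha
    records: pd.DataFrame  # weight_correlations table with in_panel flag


def select_panel(
    records: pd.DataFrame, r_cut: float = 0.75, alpha: float = 0.05
) -> PanelSelection:
    """Cut the biomarker panel at r >= r_cut (inclusive) and p < alpha."""
    if not 0 < r_cut < 1:
        raise ValueError("r_cut must be in (0, 1)")
    ok = records["defined"]
    in_panel = ok & (records["r"] >= r_cut) & (records["p"] < alpha) & (records["r"] > 0)
    positive = ok & (records["r"] > 0) & (records["p"] < alpha)
    if not in_panel.any():
        logger.warning("biomarker panel is empty at r >= %.2f, p < %.2f", r_cut, alpha)
    rec = records.assign(in_panel=in_panel)
    return PanelSelection(
        panel=set(records.index[in_panel]),
        positive_significant=set(records.index[positive]),
        records=rec,
    )
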