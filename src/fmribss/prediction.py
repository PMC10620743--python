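"""Sparse-regression prediction of behavioral targets from network voxels.

Feature selection follows the connectome-based predictive modeling (CPM)
idea applied to spatial maps: each voxel of a network's subject maps is
Pearson-correlated with the target (after residualizing both on nuisance
covariates) and kept when its two-sided p falls below a strict threshold
(default 0.001). Prediction uses LASSO — objective
(1/2N) ||X w - y||^2 + alpha ||w||_1 — inside a nested cross-validation:
leave-one-out outer folds, 10-fold inner folds choosing alpha on a
log-spaced path. By default feature selection is re-run inside every
outer training fold (leakage-safe); ``selection="pooled"`` restores the
select-once-on-all-subjects ordering for comparison.

Performance is summarized by R^2, RMSE and Spearman's rho, with a
permutation test on the predicted-vs-observed Spearman correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from .network import residualize_covariates

logger = logging.getLogger(__name__)


@dataclass
class FeatureSelection:
    network_id: str
    voxel_indices: np.ndarray
    correlations: np.ndarray
    pvalues: np.ndarray
    threshold: float

    @property
    def n_selected(self) -> int:
        return int(self.voxel_indices.size)


def _pearson_with_p(features: np.ndarray, target: np.ndarray):
    """Columnwise Pearson r of features (N x V) with target (N,), and
    two-sided p from the t distribution with N - 2 df."""
    n = target.size
    fz = features - features.mean(axis=0)
    tz = target - target.mean()
    denom = np.sqrt((fz ** 2).sum(axis=0) * (tz ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, fz.T @ tz / denom, 0.0)
    r = np.clip(r, -0.9999999999, 0.9999999999)
    t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    return r, p


def cpm_select(features: np.ndarray, target: np.ndarray,
               p_threshold: float = 0.001, covariates: np.ndarray = None,
               network_id: str = "") -> FeatureSelection:
    """Correlation-thresholded voxel selection: residualize the target and
    every voxel on the covariates (if any), Pearson-correlate, and keep
    voxels with two-sided p strictly below ``p_threshold``.

    An empty selection is returned as a zero-length FeatureSelection (the
    caller skips the network)."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    if x.shape[0] < 10:
        raise ValueError("need at least 10 subjects")
    if np.all(y == y[0]):
        raise ValueError("constant target")
    if covariates is not None and np.asarray(covariates).size:
        y = residualize_covariates(y, covariates)
        x = residualize_covariates(x, covariates)
    r, p = _pearson_with_p(x, y)
    keep = np.where(p < p_threshold)[0]
    if keep.size == 0:
        logger.info("network %s: no voxels at p < %g", network_id, p_threshold)
    return FeatureSelection(
        network_id=network_id, voxel_indices=keep,
        correlations=r[keep], pvalues=p[keep], threshold=p_threshold,
    )


@dataclass
class PredictionResult:
    target_name: str
    predictions: np.ndarray
    observed: np.ndarray
    r2: float
    rmse: float
    spearman_rho: float
    permutation_p: float = None
    alphas: list = field(default_factory=list)
    seed: int = 0
    n_selected_per_fold: list = field(default_factory=list)


def make_alpha_grid(x: np.ndarray, y: np.ndarray, n_alphas: int = 100,
                    eps: float = 1e-4) -> np.ndarray:
    """Log-spaced LASSO path from alpha_max (smallest alpha zeroing all
    coefficients, max|X^T y| / N on centered data) down to eps*alpha_max."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    alpha_max = np.max(np.abs(xc.T @ yc)) / x.shape[0]
    if alpha_max <= 0:
        alpha_max = 1.0
    return np.logspace(np.log10(alpha_max * eps), np.log10(alpha_max), n_alphas)


def _standardize_train_test(x_train, x_test):
    mean = x_train.mean(axis=0)
    sd = x_train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x_train - mean) / sd, (x_test - mean) / sd


def _fit_predict_fold(x_train, y_train, x_test, alpha_grid, seed):
    """Inner 10-fold CV over the alpha grid, refit on the full training
    fold, predict the held-out rows. Returns (predictions, chosen alpha)."""
    xs, xt = _standardize_train_test(x_train, x_test)
    if alpha_grid is None:
        grid = make_alpha_grid(xs, y_train)
    else:
        grid = np.asarray(alpha_grid, dtype=float)
    n_splits = min(10, len(y_train))
    cv = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    # loose tol/max_iter: CV model selection does not need 1e-6 objectives
    model = LassoCV(alphas=grid, cv=cv, max_iter=500, tol=1e-3,
                    precompute=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(xs, y_train)
    return model.predict(xt), float(model.alpha_)


def lasso_nested_cv(x: np.ndarray, y: np.ndarray, alpha_grid=None,
                    seed: int = 0, target_name: str = "") -> PredictionResult:
    """Nested cross-validated LASSO on a fixed feature matrix: outer
    leave-one-out, inner 10-fold CV picking alpha; features standardized
    within each training fold only."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("need at least one feature")
    n = y.size
    if n < 12:
        raise ValueError("need at least 12 subjects for nested CV")
    if np.all(y == y[0]):
        raise ValueError("constant target")
    preds = np.empty(n)
    alphas = []
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        pred, alpha = _fit_predict_fold(
            x[train], y[train], x[~train], alpha_grid, seed)
        preds[i] = pred[0]
        alphas.append(alpha)
    r2, rmse, rho = evaluate_prediction(y, preds)
    return PredictionResult(
        target_name=target_name, predictions=preds, observed=y,
        r2=r2, rmse=rmse, spearman_rho=rho, alphas=alphas, seed=seed,
    )


def predict_network(features: np.ndarray, target: np.ndarray,
                    covariates: np.ndarray = None, p_threshold: float = 0.001,
                    alpha_grid=None, seed: int = 0,
                    selection: str = "nested", target_name: str = "",
                    network_id: str = "") -> PredictionResult:
    """Full per-network prediction: CPM voxel selection + nested-CV LASSO.

    selection="nested" (default) re-selects voxels inside every outer
    training fold, so the held-out subject never influences its own
    feature set; selection="pooled" selects once on all subjects before
    the outer loop (optimistically biased — provided for comparison).
    Returns a PredictionResult, or None when no voxels survive selection.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    n = y.size
    if n < 12:
        raise ValueError("need at least 12 subjects")
    if selection == "pooled":
        sel = cpm_select(x, y, p_threshold, covariates, network_id)
        if sel.n_selected == 0:
            return None
        result = lasso_nested_cv(x[:, sel.voxel_indices], y,
                                 alpha_grid=alpha_grid, seed=seed,
                                 target_name=target_name)
        result.n_selected_per_fold = [sel.n_selected] * n
        return result
    if selection != "nested":
        raise ValueError(f"unknown selection mode {selection!r}")

    preds = np.empty(n)
    alphas, n_sel = [], []
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        cov_train = None if covariates is None else np.asarray(covariates)[train]
        sel = cpm_select(x[train], y[train], p_threshold, cov_train, network_id)
        n_sel.append(sel.n_selected)
        if sel.n_selected == 0:
            # no informative voxels in this fold: predict the training mean
            preds[i] = y[train].mean()
            alphas.append(np.nan)
            continue
        cols = sel.voxel_indices
        pred, alpha = _fit_predict_fold(
            x[train][:, cols], y[train], x[~train][:, cols], alpha_grid, seed)
        preds[i] = pred[0]
        alphas.append(alpha)
    if max(n_sel) == 0:
        return None
    r2, rmse, rho = evaluate_prediction(y, preds)
    return PredictionResult(
        target_name=target_name, predictions=preds, observed=y,
        r2=r2, rmse=rmse, spearman_rho=rho, alphas=alphas, seed=seed,
        n_selected_per_fold=n_sel,
    )


def evaluate_prediction(y, y_hat):
    """(R^2, RMSE, Spearman rho) of predictions against observations.
    R^2 = 1 - SS_res/SS_tot; a constant observed vector is an error."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size != y_hat.size or y.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        raise ValueError("constant observed values: R^2 undefined")
    r2 = 1.0 - ((y - y_hat) ** 2).sum() / ss_tot
    rmse = float(np.sqrt(((y - y_hat) ** 2).mean()))
    if np.all(y_hat == y_hat[0]):
        rho = 0.0
    else:
        rho = float(stats.spearmanr(y, y_hat).statistic)
    return float(r2), rmse, rho


def permutation_test_prediction(y, y_hat, n_perm: int = 1000,
                                seed: int = 0) -> float:
    """One-sided permutation p for the predicted-vs-observed Spearman
    correlation: permute one vector n_perm times,
    p = (1 + #{rho_perm >= rho_obs}) / (1 + n_perm)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size < 10:
        raise ValueError("need at least 10 observations")
    rng = np.random.default_rng(seed)
    ry = stats.rankdata(y)
    rh = stats.rankdata(y_hat)
    ry_c = ry - ry.mean()
    rh_c = rh - rh.mean()
    denom = np.sqrt((ry_c ** 2).sum() * (rh_c ** 2).sum())
    if denom == 0:
        return 1.0
    obs = float(ry_c @ rh_c / denom)
    order = np.argsort(rng.random((n_perm, y.size)), axis=1)
    null = (rh_c[order] @ ry_c) / denom
    count = int((null >= obs - 1e-15).sum())
    return float((1 + count) / (1 + n_perm))
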