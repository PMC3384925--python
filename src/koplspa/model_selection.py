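"""Stratified cross-validation and (sigma, Ao) grid search for K-OPLS.

The search criterion is ACCV — accuracy of classification of
cross-validation — pooled over all held-out folds. Ties between grid points
are broken by parsimony: smallest Ao first, then smallest sigma. Autoscaling
is refitted inside every training fold so that no held-out information leaks
into the scaling statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kopls import FitStats, classify, fit_kopls_xy, fit_stats, predict_kopls
from .preprocess import AutoScaler

#: Default sigma grid: log-spaced points spanning the conventional 0.1-10 range.
DEFAULT_SIGMA_GRID = (0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0)
DEFAULT_AO_GRID = tuple(range(1, 11))


def stratified_kfold(labels: np.ndarray, k: int = 10, seed: int = 0) -> np.ndarray:
    """Assign samples to k folds, stratified by class and balanced in size.

    Each class's members are spread across folds so that per-fold class
    counts differ by at most one; classes' remainders are placed on the
    currently lightest folds so per-fold totals also differ by at most one.
    Returns an integer fold index per sample.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(labels, return_counts=True)
    small = counts.min()
    if small < k:
        raise ValueError(f"smallest class has {small} samples, fewer than k={k}")
    assignment = np.empty(labels.shape[0], dtype=int)
    fold_totals = np.zeros(k, dtype=int)
    # larger classes first so their remainders are balanced by smaller ones
    for c in classes[np.argsort(-counts, kind="stable")]:
        members = np.flatnonzero(labels == c)
        members = rng.permutation(members)
        base, extra = divmod(members.size, k)
        # folds receiving one extra member: the lightest ones, random among ties
        order = rng.permutation(k)
        order = order[np.argsort(fold_totals[order], kind="stable")]
        sizes = np.full(k, base, dtype=int)
        sizes[order[:extra]] += 1
        start = 0
        for fold in range(k):
            assignment[members[start : start + sizes[fold]]] = fold
            start += sizes[fold]
        fold_totals += sizes
    return assignment


@dataclass
class CVGridResult:
    """Full ACCV grid with the selected (sigma, Ao) and its fit statistics."""

    grid: pd.DataFrame  # columns: sigma, Ao, accv
    best_sigma: float
    best_Ao: int
    best_accv: float
    fold_assignments: np.ndarray
    stats: FitStats | None = None


def _cv_predictions(
    X: np.ndarray,
    labels: np.ndarray,
    sigma: float,
    Ao: int,
    folds: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Held-out decision values and predicted labels for every sample.

    Scaling and model fitting use the training folds only.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    decisions = np.empty(n, dtype=float)
    predicted = np.empty(n, dtype=np.asarray(labels).dtype)
    for fold in np.unique(folds):
        val = folds == fold
        train = ~val
        scaler = AutoScaler().fit(X[train])
        model = fit_kopls_xy(scaler.transform(X[train]), labels[train], sigma, Ao)
        yhat, _ = predict_kopls(model, scaler.transform(X[val]))
        decisions[val] = yhat + model.y_offset
        predicted[val] = classify(model, yhat)
    return decisions, predicted


def grid_search(
    X: np.ndarray,
    labels: np.ndarray,
    sigma_grid=DEFAULT_SIGMA_GRID,
    ao_grid=DEFAULT_AO_GRID,
    k: int = 10,
    seed: int = 0,
    folds: np.ndarray | None = None,
    compute_stats: bool = True,
) -> CVGridResult:
    """Exhaustive ACCV search over the (sigma, Ao) grid.

    ``X`` holds unscaled features (e.g. concentration ratios); every training
    fold is autoscaled with its own statistics. ACCV is the pooled fraction
    of correctly classified held-out samples over all k folds.
    """
    sigma_grid = [float(s) for s in sigma_grid]
    ao_grid = [int(a) for a in ao_grid]
    if not sigma_grid or not ao_grid:
        raise ValueError("sigma_grid and ao_grid must be non-empty")
    labels = np.asarray(labels)
    if folds is None:
        folds = stratified_kfold(labels, k=k, seed=seed)
    rows = []
    for sigma in sigma_grid:
        for ao in ao_grid:
            try:
                _, predicted = _cv_predictions(X, labels, sigma, ao, folds)
            except ValueError as err:
                raise ValueError(
                    f"grid point (sigma={sigma}, Ao={ao}) failed: {err}"
                ) from err
            accv = float(np.mean(predicted == labels))
            rows.append({"sigma": sigma, "Ao": ao, "accv": accv})
    grid = pd.DataFrame(rows)
    # maximize ACCV; break ties toward small Ao, then small sigma
    order = grid.sort_values(
        ["accv", "Ao", "sigma"], ascending=[False, True, True], kind="stable"
    )
    best = order.iloc[0]
    result = CVGridResult(
        grid=grid,
        best_sigma=float(best["sigma"]),
        best_Ao=int(best["Ao"]),
        best_accv=float(best["accv"]),
        fold_assignments=folds,
    )
    if compute_stats:
        scaler = AutoScaler().fit(X)
        model = fit_kopls_xy(
            scaler.transform(X), labels, result.best_sigma, result.best_Ao
        )
        coded = np.where(labels == model.classes_[1], 1.0, -1.0)
        decisions, _ = _cv_predictions(X, labels, result.best_sigma, result.best_Ao, folds)
        result.stats = fit_stats(model, cv_y=coded, cv_pred=decisions)
    return result


def cross_validated_q2y(
    X: np.ndarray,
    labels: np.ndarray,
    sigma: float,
    Ao: int,
    k: int = 10,
    seed: int = 0,
    folds: np.ndarray | None = None,
) -> float:
    """Q2Y = 1 - PRESS/SS from held-out predictions at fixed (sigma, Ao)."""
    labels = np.asarray(labels)
    if folds is None:
        folds = stratified_kfold(labels, k=k, seed=seed)
    decisions, _ = _cv_predictions(X, labels, sigma, Ao, folds)
    classes = np.unique(labels)
    coded = np.where(labels == classes[1], 1.0, -1.0)
    press = float(np.sum((coded - decisions) ** 2))
    ss = float(np.sum((coded - coded.mean()) ** 2))
    return 1.0 - press / ss
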