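"""Subwindow permutation analysis (SPA) for informative-metabolite selection.

SPA builds a population of K-OPLS submodels by Monte-Carlo sampling in both
sample space (a stratified calibration draw of a fraction R of the cohort)
and variable space (a random subwindow of Q metabolites). For every
submodel the normal prediction error (misclassification fraction on the
validation samples) is recorded, and for each metabolite in the subwindow a
permuted error is recorded after shuffling that metabolite's values among
the validation samples. Per metabolite, the mean normal error MEAN_A, mean
permuted error MEAN_B and their difference DMEAN = MEAN_B - MEAN_A are
computed; a one-sided Mann-Whitney U test (permuted errors stochastically
larger) gives a conditional P value, transformed into the Conditional
Synergetic Score

    COSS = -log10(P)        if DMEAN > 0
    COSS = -log10(P + 1)    if DMEAN <= 0,

so that P < 0.01 with a positive DMEAN corresponds to COSS > 2. Selection
proceeds in three steps: drop DMEAN < 0, rank the rest by P, flag P below
the threshold as informative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clinical import pooled_t_from_summary  # noqa: F401  (cross-check twin)
from .kopls import classify, fit_kopls_xy, predict_kopls
from .preprocess import AutoScaler

_MAX_REDRAWS = 100


@dataclass
class SPAConfig:
    """Monte-Carlo and submodel parameters for SPA.

    N submodels, calibration fraction R, Q variables per subwindow, and the
    K-OPLS hyperparameters (sigma, ao) used in every submodel — normally the
    pair selected by the external cross-validated grid search.
    """

    N: int = 1000
    R: float = 0.8
    Q: int = 8
    p_threshold: float = 0.01
    sigma: float = 0.5
    ao: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.R < 1:
            raise ValueError("R must be in (0, 1)")
        if self.N < 1:
            raise ValueError("N must be at least 1")
        if self.Q < 1:
            raise ValueError("Q must be at least 1")


@dataclass
class MetaboliteScore:
    """Per-metabolite SPA summary."""

    name: str
    n_models: int
    mean_A: float
    mean_B: float
    dmean: float
    u_stat: float
    p_value: float
    coss: float
    informative: bool = False
    t_p: float = field(default=float("nan"))


def mann_whitney_u(
    sample_A, sample_B, method: str = "auto"
) -> tuple[float, float]:
    """One-sided Mann-Whitney U test of B stochastically larger than A.

    Exact null enumeration when the smaller sample has at most 8 values and
    the pooled data are tie-free; otherwise the normal approximation with
    tie and continuity corrections. Returns (U of sample A, P value).
    """
    a = np.asarray(sample_A, dtype=float)
    b = np.asarray(sample_B, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if method == "auto":
        pooled = np.concatenate([a, b])
        tie_free = np.unique(pooled).size == pooled.size
        method = "exact" if (min(a.size, b.size) <= 8 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="less", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def compute_coss(p_value: float, dmean: float) -> float:
    """Conditional Synergetic Score from the conditional P value and DMEAN."""
    if p_value <= 0:
        warnings.warn("non-positive P value clamped for COSS", RuntimeWarning)
        p_value = np.nextafter(0.0, 1.0)
    if p_value > 1:
        raise ValueError("P value must be at most 1")
    if dmean > 0:
        return -math.log10(p_value)
    return -math.log10(p_value + 1.0)


def _stratified_split(
    labels: np.ndarray, R: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Calibration/validation split: ceil(R*n) samples, stratified by class.

    The total calibration size is apportioned to classes by largest
    remainder, so both the draw size contract and stratification hold.
    """
    n = labels.shape[0]
    n_cal = math.ceil(R * n)
    classes, counts = np.unique(labels, return_counts=True)
    quota = counts * n_cal / n
    base = np.floor(quota).astype(int)
    short = n_cal - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:short]] += 1
    cal_parts, val_parts = [], []
    for c, take in zip(classes, base):
        members = rng.permutation(np.flatnonzero(labels == c))
        cal_parts.append(members[:take])
        val_parts.append(members[take:])
    return np.concatenate(cal_parts), np.concatenate(val_parts)


def prediction_errors_for_run(
    X: np.ndarray,
    labels: np.ndarray,
    cal_idx: np.ndarray,
    val_idx: np.ndarray,
    var_idx: np.ndarray,
    sigma: float,
    ao: int,
    rng: np.random.Generator,
) -> tuple[float, dict[int, float]]:
    """Normal and per-variable permuted errors for one SPA submodel.

    Fits K-OPLS on the calibration rows restricted to ``var_idx`` (scaled
    with calibration statistics), classifies the validation rows, then for
    each subwindow variable permutes its validation values once (the fitted
    model is untouched) and re-classifies. Errors are misclassification
    fractions on the validation set.
    """
    Xc = X[np.ix_(cal_idx, var_idx)]
    Xv = X[np.ix_(val_idx, var_idx)]
    y_cal, y_val = labels[cal_idx], labels[val_idx]
    scaler = AutoScaler().fit(Xc)
    model = fit_kopls_xy(scaler.transform(Xc), y_cal, sigma, ao)

    def _error(Xval_raw: np.ndarray) -> float:
        yhat, _ = predict_kopls(model, scaler.transform(Xval_raw))
        return float(np.mean(classify(model, yhat) != y_val))

    normal_error = _error(Xv)
    permuted: dict[int, float] = {}
    for pos, j in enumerate(var_idx):
        Xp = Xv.copy()
        Xp[:, pos] = Xp[rng.permutation(Xp.shape[0]), pos]
        permuted[int(j)] = _error(Xp)
    return normal_error, permuted


def run_spa(
    X: np.ndarray,
    labels: np.ndarray,
    metabolite_names: list[str],
    config: SPAConfig,
) -> list[MetaboliteScore]:
    """Run the full subwindow permutation analysis.

    ``X`` holds unscaled features (e.g. concentration ratios); each submodel
    autoscales its calibration subwindow and applies those statistics to the
    validation rows. Fully deterministic under ``config.seed``.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n, p = X.shape
    if config.Q > p:
        raise ValueError(f"Q={config.Q} exceeds the number of variables p={p}")
    if len(metabolite_names) != p:
        raise ValueError("metabolite_names length mismatch")
    rng = np.random.default_rng(config.seed)
    normal_errors: list[list[float]] = [[] for _ in range(p)]
    permuted_errors: list[list[float]] = [[] for _ in range(p)]
    for _ in range(config.N):
        for attempt in range(_MAX_REDRAWS + 1):
            cal_idx, val_idx = _stratified_split(labels, config.R, rng)
            ok = (
                np.unique(labels[cal_idx]).size == 2
                and np.unique(labels[val_idx]).size == 2
            )
            if ok:
                break
        else:
            raise RuntimeError(
                "could not draw a calibration/validation split containing "
                "both classes; groups too small for the requested R"
            )
        var_idx = np.sort(rng.choice(p, size=config.Q, replace=False))
        err, permuted = prediction_errors_for_run(
            X, labels, cal_idx, val_idx, var_idx, config.sigma, config.ao, rng
        )
        for j in var_idx:
            normal_errors[j].append(err)
            permuted_errors[j].append(permuted[int(j)])

    t_ps = ttest_crosscheck(X, labels)
    scores = []
    for j, name in enumerate(metabolite_names):
        a = np.asarray(normal_errors[j])
        b = np.asarray(permuted_errors[j])
        if a.size == 0:
            scores.append(
                MetaboliteScore(name, 0, float("nan"), float("nan"), float("nan"),
                                float("nan"), float("nan"), float("nan"),
                                t_p=t_ps[j])
            )
            continue
        mean_a, mean_b = float(a.mean()), float(b.mean())
        dmean = mean_b - mean_a
        u, pval = mann_whitney_u(a, b)
        scores.append(
            MetaboliteScore(
                name=name,
                n_models=int(a.size),
                mean_A=mean_a,
                mean_B=mean_b,
                dmean=dmean,
                u_stat=u,
                p_value=pval,
                coss=compute_coss(pval, dmean),
                t_p=t_ps[j],
            )
        )
    return select_informative(scores, config.p_threshold)


def select_informative(
    scores: list[MetaboliteScore], p_threshold: float = 0.01
) -> list[MetaboliteScore]:
    """Apply the three-step selection rule and order the output.

    Metabolites with DMEAN < 0 are removed from consideration before any
    significance decision; the remainder are ranked by ascending P and
    flagged informative below the threshold. Output order: informative by
    ascending P, then the remaining candidates, then the removed ones.
    """
    def sort_key(s: MetaboliteScore):
        p = s.p_value if np.isfinite(s.p_value) else np.inf
        return (s.dmean < 0 or not np.isfinite(s.dmean), p)

    ordered = sorted(scores, key=sort_key)
    for s in ordered:
        s.informative = bool(
            np.isfinite(s.dmean)
            and s.dmean >= 0
            and np.isfinite(s.p_value)
            and s.p_value < p_threshold
        )
    return ordered


def ttest_crosscheck(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Two-sided pooled-variance t-test P value per metabolite column."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    g1, g2 = X[labels == classes[0]], X[labels == classes[1]]
    if g1.shape[0] < 2 or g2.shape[0] < 2:
        raise ValueError("both groups need at least 2 samples")
    res = stats.ttest_ind(g1, g2, axis=0, equal_var=True)
    return np.asarray(res.pvalue, dtype=float)


def scores_to_frame(scores: list[MetaboliteScore]) -> pd.DataFrame:
    """Machine-readable SPA table: one row per metabolite."""
    return pd.DataFrame(
        [
            {
                "metabolite": s.name,
                "n_models": s.n_models,
                "mean_A": s.mean_A,
                "mean_B": s.mean_B,
                "dmean": s.dmean,
                "U": s.u_stat,
                "P": s.p_value,
                "COSS": s.coss,
                "informative": s.informative,
                "t_test_P": s.t_p,
            }
            for s in scores
        ]
    )
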