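"""Group-comparison statistics for clinical covariate tables.

Continuous variables are compared with pooled-variance (Student) two-sample
t-tests; categorical variables with Pearson's chi-square without continuity
correction, falling back to Fisher's exact test when any expected cell
count is below 5. Display formatting follows clinical-table convention:
percentages to one decimal, P values to three decimals floored at "<0.001".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def pooled_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Two-sample pooled-variance t-test from group summaries.

    Returns (t, df, two-sided P) with df = n1 + n2 - 2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd1 < 0 or sd2 < 0 or (sd1 == 0 and sd2 == 0):
        raise ValueError("SDs must be non-negative and not both zero")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=True
    )
    return float(res.statistic), n1 + n2 - 2, float(res.pvalue)


def _check_2x2(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table of counts")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin in 2x2 table")
    return t


def expected_counts(table) -> np.ndarray:
    """Expected cell counts under independence for a 2x2 table."""
    t = _check_2x2(table)
    return np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()


def pearson_chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction, df = 1."""
    t = _check_2x2(table)
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), int(df), float(p)


def fishers_exact(table) -> float:
    """Two-sided Fisher's exact P (sum of hypergeometric probabilities
    no larger than the observed table's)."""
    t = _check_2x2(table)
    _, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
    return float(p)


def format_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def format_percent(count: int, total: int) -> str:
    return f"{100.0 * count / total:.1f}%"


@dataclass
class ClinicalSummary:
    """Per-variable group summaries, test used, and P values."""

    table: pd.DataFrame  # variable, type, group1, group2, test, P, P_display


def _is_binary(x: np.ndarray) -> bool:
    vals = np.unique(x[~pd.isna(x)])
    return vals.size <= 2 and np.all(np.isin(vals, vals.astype(int)))


def build_table(
    clinical: pd.DataFrame,
    labels,
    variable_types: dict[str, str] | None = None,
) -> ClinicalSummary:
    """Build a group-comparison table for every covariate column.

    ``labels`` is either a column name in ``clinical`` or an array of binary
    group labels. ``variable_types`` can force 'continuous'/'categorical'
    per variable; by default columns with at most two integer-valued levels
    are treated as categorical. Variables whose 2x2 table has a zero margin
    are skipped with a warning.
    """
    if isinstance(labels, str):
        y = clinical[labels].to_numpy()
        columns = [c for c in clinical.columns if c != labels]
    else:
        y = np.asarray(labels)
        columns = list(clinical.columns)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("labels must take exactly two values")
    g1, g2 = y == classes[1], y == classes[0]
    variable_types = variable_types or {}

    rows = []
    for col in columns:
        x = clinical[col].to_numpy()
        if pd.isna(x).any():
            raise ValueError(f"variable {col!r} has missing values")
        vtype = variable_types.get(
            col, "categorical" if _is_binary(x.astype(float)) else "continuous"
        )
        if vtype == "continuous":
            m1, s1, n1 = x[g1].mean(), x[g1].std(ddof=1), int(g1.sum())
            m2, s2, n2 = x[g2].mean(), x[g2].std(ddof=1), int(g2.sum())
            _, _, p = pooled_t_from_summary(m1, s1, n1, m2, s2, n2)
            rows.append(
                {
                    "variable": col,
                    "type": "continuous",
                    "group1": f"{m1:.2f} ± {s1:.2f}",
                    "group2": f"{m2:.2f} ± {s2:.2f}",
                    "test": "pooled t",
                    "P": p,
                    "P_display": format_p(p),
                }
            )
        elif vtype == "categorical":
            xb = x.astype(float)
            pos = xb == np.max(xb)
            counts = np.array(
                [
                    [int((pos & g1).sum()), int((~pos & g1).sum())],
                    [int((pos & g2).sum()), int((~pos & g2).sum())],
                ]
            )
            try:
                _check_2x2(counts)
            except ValueError as err:
                warnings.warn(f"skipping variable {col!r}: {err}", UserWarning)
                continue
            if np.any(expected_counts(counts) < 5):
                p = fishers_exact(counts)
                test = "Fisher exact"
            else:
                _, _, p = pearson_chi_square(counts)
                test = "Pearson chi-square"
            n1, n2 = int(g1.sum()), int(g2.sum())
            rows.append(
                {
                    "variable": col,
                    "type": "categorical",
                    "group1": f"{format_percent(counts[0, 0], n1)}({counts[0, 0]}/{n1})",
                    "group2": f"{format_percent(counts[1, 0], n2)}({counts[1, 0]}/{n2})",
                    "test": test,
                    "P": p,
                    "P_display": format_p(p),
                }
            )
        else:
            raise ValueError(f"unknown variable type {vtype!r} for {col!r}")
    return ClinicalSummary(table=pd.DataFrame(rows))
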