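"""Baseline-comparison statistics: Wilcoxon rank-sum and chi-square tests.

These reproduce the descriptive arm comparisons of a randomized-trial
baseline table: mean (SD) with Wilcoxon rank-sum tests for continuous
variables, n (%) with Pearson chi-square tests for proportions. Two-sided
throughout; significance is conventionally read at p ≤ 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import (
    BINARY_COVARIATES,
    CATEGORICAL_COVARIATES,
    CONTINUOUS_COVARIATES,
    OUTCOMES,
)


@dataclass(frozen=True)
class BaselineComparison:
    """One row of a baseline table: per-arm summaries and a two-sided test."""

    variable: str
    summary_early: str
    summary_late: str
    test: str  # "wilcoxon" or "chi_square"
    statistic: float
    p_value: float


def chi_square_test(table, *, continuity: bool = False) -> tuple[float, float]:
    """Pearson chi-square test of homogeneity on a 2×K (or R×C) count table.

    No continuity correction by default (``continuity=True`` enables Yates
    for 2×2 tables). Returns ``(statistic, p_value)`` with
    df = (rows−1)(cols−1).

    Raises ``ValueError`` on a degenerate table (any zero row/column margin).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need an R×C table with R, C ≥ 2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero row or column margin")
    stat, p, _, _ = sps.chi2_contingency(t, correction=continuity)
    return float(stat), float(p)


def wilcoxon_rank_sum(
    x, y, *, method: str = "auto"
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test with midranks for ties.

    Returns ``(W, p)`` where W is the rank-sum of the first sample. The
    p-value is exact (full enumeration) when ``n+m ≤ 12`` and there are no
    ties, otherwise a normal approximation with tie and continuity
    correction
    (``method`` forces ``"exact"`` or ``"normal"``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if method == "auto":
        method = "exact" if (len(pooled) <= 12 and not has_ties) else "normal"
    if method == "exact" and has_ties:
        raise ValueError("exact enumeration requires tie-free data")
    scipy_method = "exact" if method == "exact" else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=scipy_method, use_continuity=True
    )
    # rank-sum of x from the Mann-Whitney U statistic
    w = float(res.statistic) + len(x) * (len(x) + 1) / 2.0
    return w, float(res.pvalue)


def _fmt_mean_sd(v: np.ndarray) -> str:
    v = v[~np.isnan(v)]
    return f"{v.mean():.2f} ({v.std(ddof=1):.2f})" if len(v) > 1 else "–"


def _category_counts(values: pd.Series) -> pd.Series:
    """Counts per level, missing values reported as an 'Unknown' level."""
    s = values.astype("object").where(~values.isna(), "Unknown")
    return s.value_counts()


def baseline_table(
    cohort: pd.DataFrame, variables: list[str] | None = None
) -> list[BaselineComparison]:
    """Arm-comparison table over ``variables`` (default: all covariates
    and outcomes).

    Continuous variables get mean (SD) and a Wilcoxon rank-sum p; categorical
    and binary variables get n (%) and a chi-square p over the full level ×
    arm contingency table (missing categories counted as "Unknown").
    """
    if variables is None:
        variables = list(
            CONTINUOUS_COVARIATES
            + tuple(
                c for c in CATEGORICAL_COVARIATES
            )
            + BINARY_COVARIATES
            + OUTCOMES
        )
    early = cohort[cohort["arm"] == "early-PN"]
    late = cohort[cohort["arm"] == "late-PN"]
    rows: list[BaselineComparison] = []
    continuous = set(CONTINUOUS_COVARIATES) | set(OUTCOMES)
    for var in variables:
        if var not in cohort.columns:
            raise KeyError(f"unknown variable {var!r}")
        if var in continuous or cohort[var].dtype.kind == "f":
            xe = early[var].to_numpy(float)
            xl = late[var].to_numpy(float)
            xe, xl = xe[~np.isnan(xe)], xl[~np.isnan(xl)]
            stat, p = wilcoxon_rank_sum(xe, xl)
            rows.append(
                BaselineComparison(
                    var, _fmt_mean_sd(xe), _fmt_mean_sd(xl), "wilcoxon", stat, p
                )
            )
        else:
            ce = _category_counts(early[var])
            cl = _category_counts(late[var])
            levels = sorted(set(ce.index) | set(cl.index))
            tab = np.array(
                [[ce.get(l, 0) for l in levels], [cl.get(l, 0) for l in levels]],
                dtype=float,
            )
            keep = tab.sum(axis=0) > 0
            tab = tab[:, keep]
            if tab.shape[1] < 2:  # single observed level: no contrast
                stat, p = 0.0, 1.0
            else:
                stat, p = chi_square_test(tab)
            fmt = lambda c, n: "; ".join(
                f"{l}: {int(c.get(l, 0))} ({100 * c.get(l, 0) / max(n, 1):.0f}%)"
                for l in levels
            )
            rows.append(
                BaselineComparison(
                    var, fmt(ce, len(early)), fmt(cl, len(late)), "chi_square", stat, p
                )
            )
    return rows


def baseline_markdown(rows: list[BaselineComparison]) -> str:
    """Baseline comparisons as a Markdown pipe table."""
    lines = [
        "| Variable | Early-PN | Late-PN | Test | Statistic | p |",
        "|---|---|---|---|---|---|",
    ]
    for r in rows:
        lines.append(
            f"| {r.variable} | {r.summary_early} | {r.summary_late} | "
            f"{r.test} | {r.statistic:.3f} | {r.p_value:.4g} |"
        )
    return "\n".join(lines) + "\n"


def baseline_frame(rows: list[BaselineComparison]) -> pd.DataFrame:
    """Baseline comparisons as a DataFrame (for CSV / Markdown export)."""
    return pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "early_PN": [r.summary_early for r in rows],
            "late_PN": [r.summary_late for r in rows],
            "test": [r.test for r in rows],
            "statistic": [r.statistic for r in rows],
            "p_value": [r.p_value for r in rows],
        }
    )
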