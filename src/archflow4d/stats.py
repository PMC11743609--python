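"""Cohort statistics: exact contingency tests and group comparisons.

The statistical layer of a small two-group cohort study: two-sided
Fisher exact tests on 2x2 tables (computed in log space by hypergeometric
enumeration), Mann-Whitney U comparisons with an exact/asymptotic
crossover, Pearson correlations, and an assembler that turns a cohort
table into a group-comparison report (median [IQR] + Mann-Whitney p for
continuous endpoints, counts (%) + Fisher p for binary ones).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import logsumexp

__all__ = [
    "ContingencyTable2x2", "fisher_exact_2x2", "fisher_point_log_probs",
    "mann_whitney_u", "MannWhitneyResult", "pearson_r",
    "compare_groups", "GroupComparisonReport",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = group and columns = trait."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def _as_table(table) -> ContingencyTable2x2:
    if isinstance(table, ContingencyTable2x2):
        return table
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    return ContingencyTable2x2(*arr.ravel())


def fisher_point_log_probs(table) -> tuple:
    """Log hypergeometric point probabilities of all tables with the
    margins of ``table``; returns ``(a_values, log_probs, a_observed)``."""
    t = _as_table(table)
    r1, r2 = t.a + t.b, t.c + t.d
    c1 = t.a + t.c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        # degenerate margins: only one table is possible
        return np.array([t.a]), np.array([0.0]), t.a
    lo, hi = max(0, c1 - r2), min(r1, c1)
    a_vals = np.arange(lo, hi + 1)
    logp = sps.hypergeom.logpmf(a_vals, n, r1, c1)
    return a_vals, logp, t.a


def fisher_exact_2x2(table, convention: str = "minlike") -> float:
    """Two-sided Fisher exact p-value of a 2x2 table.

    The default ``minlike`` convention sums the point probabilities of
    every table (margins fixed) that is no more probable than the
    observed one (with a relative slack of 1e-7 for floating-point
    ties); ``doubling`` doubles the smaller one-sided tail instead.
    Computation is done in log space for numerical safety.
    """
    a_vals, logp, a_obs = fisher_point_log_probs(table)
    log_obs = float(logp[a_vals == a_obs][0])
    if convention == "minlike":
        keep = logp <= log_obs + np.log1p(1e-7)
        p = float(np.exp(logsumexp(logp[keep])))
    elif convention == "doubling":
        lower = float(np.exp(logsumexp(logp[a_vals <= a_obs])))
        upper = float(np.exp(logsumexp(logp[a_vals >= a_obs])))
        p = 2.0 * min(lower, upper)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return min(p, 1.0)


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float          # U statistic of the first sample
    p: float          # two-sided
    method: str       # 'exact' or 'asymptotic'


def mann_whitney_u(x, y, exact_max_n: int = 16) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when the combined sample size is
    at most ``exact_max_n`` and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.  The reported U
    is that of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= exact_max_n and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return MannWhitneyResult(float(res.statistic), float(res.pvalue),
                                 "exact")
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
    return MannWhitneyResult(float(res.statistic), float(res.pvalue),
                             "asymptotic")


def pearson_r(x, y) -> tuple:
    """Pearson product-moment correlation with its two-sided p-value.

    The p-value comes from the t transform with n - 2 degrees of
    freedom; requires n >= 3 and non-degenerate variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the samples")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class GroupComparisonReport:
    """Per-endpoint group summaries and tests, Table-2 style."""

    rows: pd.DataFrame
    group_sizes: Dict[str, int]
    metadata: Dict[str, str]

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def _fmt_median_iqr(values: np.ndarray) -> str:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return f"{med:g} [{q3 - q1:g}]"


def _fmt_count_pct(k: int, n: int) -> str:
    pct = int(round(100.0 * k / n)) if n else 0
    return f"{k} ({pct})"


def compare_groups(cohort: pd.DataFrame, group_col: str,
                   endpoints: Dict[str, str],
                   exact_max_n: int = 16) -> GroupComparisonReport:
    """Two-group comparison of typed endpoints.

    ``endpoints`` maps column name to ``'continuous'`` (median [IQR] per
    group, Mann-Whitney p) or ``'binary'`` (count (%), Fisher exact p).
    Percentages are rendered as integers.  An endpoint with a single
    observed value across both groups is skipped with a flag.
    """
    groups = np.sort(cohort[group_col].unique())
    if len(groups) != 2:
        raise ValueError("group column must be binary")
    g0 = cohort[cohort[group_col] == groups[0]]
    g1 = cohort[cohort[group_col] == groups[1]]
    rows = []
    for name, kind in endpoints.items():
        x0 = g0[name].dropna().to_numpy()
        x1 = g1[name].dropna().to_numpy()
        row = {"endpoint": name, "type": kind, "test": "", "p": np.nan,
               "flag": ""}
        if len(np.unique(np.concatenate([x0, x1]))) < 2:
            row["flag"] = "constant endpoint; test skipped"
            row["group0"] = (_fmt_median_iqr(x0) if kind == "continuous"
                             else _fmt_count_pct(int(x0.sum()), len(x0)))
            row["group1"] = (_fmt_median_iqr(x1) if kind == "continuous"
                             else _fmt_count_pct(int(x1.sum()), len(x1)))
            rows.append(row)
            continue
        if kind == "continuous":
            res = mann_whitney_u(x0, x1, exact_max_n=exact_max_n)
            row.update(group0=_fmt_median_iqr(x0),
                       group1=_fmt_median_iqr(x1),
                       test=f"mann-whitney ({res.method})", p=res.p)
        elif kind == "binary":
            tab = ContingencyTable2x2(int(x1.sum()), len(x1) - int(x1.sum()),
                                      int(x0.sum()), len(x0) - int(x0.sum()))
            row.update(group0=_fmt_count_pct(int(x0.sum()), len(x0)),
                       group1=_fmt_count_pct(int(x1.sum()), len(x1)),
                       test="fisher exact", p=fisher_exact_2x2(tab))
        else:
            raise ValueError(f"unknown endpoint type {kind!r}")
        rows.append(row)
    meta = {"mann_whitney_exact_max_n": str(exact_max_n),
            "fisher_convention": "minlike"}
    return GroupComparisonReport(
        pd.DataFrame(rows, columns=["endpoint", "type", "group0", "group1",
                                    "test", "p", "flag"]),
        {"group0": len(g0), "group1": len(g1)}, meta)
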