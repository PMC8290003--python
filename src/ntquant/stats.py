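"""Cohort-level statistics for translocation scores.

Nonparametric group comparison (two-sided Mann-Whitney U, exact for small
tie-free samples, tie-corrected normal approximation otherwise), Spearman
rank correlation, group summaries (median with interquartile range), the
delta-delta-Ct relative-expression computation used as the correlate, and
thin t-test utilities. The heavy lifting is delegated to scipy; this module
fixes the exactness boundary, the two-sidedness conventions and the result
shapes so every analysis in the pipeline reports statistics the same way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "TTestResult",
    "mann_whitney_u",
    "spearman_correlation",
    "delta_delta_ct",
    "summarize_groups",
    "t_test",
    "holm_adjust",
]

# per-group size at or below which the exact Mann-Whitney null is enumerated
# (tie-free data only)
EXACT_MWU_MAX_N = 10


@dataclass
class GroupComparison:
    """A two-sample Mann-Whitney U comparison (two-sided)."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    method: str  # "exact" or "normal_approx_tie_corrected"


@dataclass
class CorrelationResult:
    """A Spearman rank correlation (two-sided)."""

    rs: float
    p_value: float
    n: int
    method: str = "t_approx"


@dataclass
class TTestResult:
    """A t test sharing the comparison-result shape (statistic is t)."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    t_statistic: float
    p_value: float
    method: str  # "student", "welch", or "paired"


def _clip_p(p: float) -> float:
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    group_a: str = "a",
    group_b: str = "b",
) -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    U is computed from mid-ranks. With both groups at most
    ``EXACT_MWU_MAX_N`` observations and no ties, the p-value comes from
    exact enumeration of the U null distribution; otherwise from the normal
    approximation with tie correction and 0.5 continuity correction. The
    ``method`` field records which path ran.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([xa, ya])
    has_ties = np.unique(combined).size < combined.size
    exact = xa.size <= EXACT_MWU_MAX_N and ya.size <= EXACT_MWU_MAX_N and not has_ties
    method = "exact" if exact else "normal_approx_tie_corrected"
    res = sps.mannwhitneyu(
        xa,
        ya,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        n_a=int(xa.size),
        n_b=int(ya.size),
        u_statistic=float(res.statistic),
        p_value=_clip_p(float(res.pvalue)),
        method=method,
    )


def spearman_correlation(
    x: Sequence[float], y: Sequence[float], exact: bool = False
) -> CorrelationResult:
    """Two-sided Spearman rank correlation.

    rs is the Pearson correlation of mid-ranks (equal to
    1 - 6*sum(d^2)/(n(n^2-1)) on tie-free data). The p-value uses the
    t-distribution approximation with n-2 degrees of freedom; with
    ``exact=True`` and n <= 8 it is instead the exact permutation p
    (fraction of the n! rank permutations with |rs| at least as large).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    n = int(xa.size)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation undefined for a constant input vector")

    rx = sps.rankdata(xa)
    ry = sps.rankdata(ya)
    rs = float(np.corrcoef(rx, ry)[0, 1])

    if exact:
        if n > 8:
            raise ValueError("exact permutation p supported only for n <= 8")
        count = 0
        total = 0
        target = abs(rs) - 1e-12
        for perm in permutations(ry):
            r = float(np.corrcoef(rx, np.asarray(perm))[0, 1])
            if abs(r) >= target:
                count += 1
            total += 1
        return CorrelationResult(
            rs=rs, p_value=_clip_p(count / total), n=n, method="exact_permutation"
        )

    if abs(rs) >= 1.0:
        return CorrelationResult(rs=rs, p_value=_clip_p(0.0), n=n)
    t = rs * math.sqrt((n - 2) / (1.0 - rs * rs))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return CorrelationResult(rs=rs, p_value=_clip_p(p), n=n)


def delta_delta_ct(
    ct_table: pd.DataFrame,
    reference_gene: str,
    calibrator_group: str,
) -> pd.DataFrame:
    """Relative expression by the delta-delta-Ct method.

    ``ct_table`` is long-format with columns sample_id, group, gene, ct
    (technical replicates are averaged). Per sample and target gene,
    dCt = Ct_target - Ct_reference; ddCt = dCt - mean dCt of the calibrator
    group; fold change = 2^(-ddCt). Returns one row per (sample, target
    gene) with columns sample_id, group, gene, delta_ct, delta_delta_ct,
    fold_change.
    """
    required = {"sample_id", "group", "gene", "ct"}
    missing_cols = required - set(ct_table.columns)
    if missing_cols:
        raise ValueError(f"ct_table missing columns: {sorted(missing_cols)}")
    table = (
        ct_table.groupby(["sample_id", "group", "gene"], as_index=False)["ct"].mean()
    )
    ref = table[table["gene"] == reference_gene].set_index("sample_id")["ct"]
    samples = table["sample_id"].unique()
    no_ref = [s for s in samples if s not in ref.index]
    if no_ref:
        raise ValueError(
            f"missing reference gene {reference_gene!r} Ct for samples: {sorted(no_ref)}"
        )
    targets = table[table["gene"] != reference_gene].copy()
    targets["delta_ct"] = targets["ct"].to_numpy() - ref.loc[
        targets["sample_id"]
    ].to_numpy()

    cal = targets[targets["group"] == calibrator_group]
    if cal.empty:
        raise ValueError(f"calibrator group {calibrator_group!r} is empty")
    cal_mean = cal.groupby("gene")["delta_ct"].mean()
    unknown = sorted(set(targets["gene"]) - set(cal_mean.index))
    if unknown:
        raise ValueError(f"no calibrator measurements for genes: {unknown}")
    targets["delta_delta_ct"] = (
        targets["delta_ct"].to_numpy() - cal_mean.loc[targets["gene"]].to_numpy()
    )
    targets["fold_change"] = 2.0 ** (-targets["delta_delta_ct"])
    out = targets[
        ["sample_id", "group", "gene", "delta_ct", "delta_delta_ct", "fold_change"]
    ]
    return out.sort_values(["gene", "sample_id"], ignore_index=True)


def summarize_groups(
    cohort: pd.DataFrame, value_column: str, by_group: str = "group"
) -> pd.DataFrame:
    """Median and interquartile range per group (linear interpolation)."""
    for col in (value_column, by_group):
        if col not in cohort.columns:
            raise ValueError(f"unknown column: {col!r}")
    rows = []
    for label, sub in cohort.groupby(by_group, sort=True):
        v = sub[value_column].to_numpy(dtype=float)
        rows.append(
            {
                by_group: label,
                "n": int(v.size),
                "median": float(np.quantile(v, 0.5)),
                "q1": float(np.quantile(v, 0.25)),
                "q3": float(np.quantile(v, 0.75)),
            }
        )
    return pd.DataFrame(rows)


def t_test(
    x: Sequence[float],
    y: Sequence[float],
    kind: str = "student",
    group_a: str = "a",
    group_b: str = "b",
) -> TTestResult:
    """Two-sided Student, Welch, or paired t test (thin scipy wrapper)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if kind == "student":
        res = sps.ttest_ind(xa, ya, equal_var=True)
    elif kind == "welch":
        res = sps.ttest_ind(xa, ya, equal_var=False)
    elif kind == "paired":
        if xa.size != ya.size:
            raise ValueError("paired t test needs equal-length samples")
        res = sps.ttest_rel(xa, ya)
    else:
        raise ValueError("kind must be 'student', 'welch', or 'paired'")
    return TTestResult(
        group_a=group_a,
        group_b=group_b,
        n_a=int(xa.size),
        n_b=int(ya.size),
        t_statistic=float(res.statistic),
        p_value=_clip_p(float(res.pvalue)),
        method=kind,
    )


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (off by default in all pipelines)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (n - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj
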