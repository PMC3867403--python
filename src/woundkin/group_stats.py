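"""Condition-level summaries and group comparison.

Per-replicate rate constants (or band fractions, migration distances)
are summarized as mean +/- sample standard deviation per condition and
compared across conditions with one-way ANOVA followed by Bonferroni
post-hoc pairwise comparisons (pooled-variance two-sample tests, raw p
multiplied by the number of pairs and capped at 1). P < 0.05 is the
conventional significance level.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats

from .errors import InsufficientDataError, InvalidInputError
from .kinetics import KineticsFit

__all__ = [
    "PairwiseComparison",
    "GroupComparison",
    "summarize",
    "one_way_anova",
    "bonferroni_pairwise",
    "compare_groups",
    "healing_report",
    "format_report",
]


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    raw_p: float
    adjusted_p: float
    significant: bool


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA over named groups plus Bonferroni pairwise results."""

    labels: Tuple[str, ...]
    means: Tuple[float, ...]
    stds: Tuple[float, ...]
    ns: Tuple[int, ...]
    f_statistic: float
    p_value: float
    pairwise: Tuple[PairwiseComparison, ...]
    alpha: float = 0.05


def summarize(values: Sequence[float]) -> Tuple[float, float, int]:
    """Arithmetic mean, sample (n-1) standard deviation, and n.

    A single observation has standard deviation 0 by convention.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InvalidInputError("cannot summarize an empty list")
    std = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return float(np.mean(v)), std, int(v.size)


def one_way_anova(groups: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Standard one-way F-test from between/within sums of squares.

    With zero variance both between and within groups the test is vacuous
    and returns (F=0, p=1); zero within-group variance with real group
    separation returns (inf, 0).
    """
    if len(groups) < 2:
        raise InsufficientDataError("ANOVA needs >= 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrs):
        raise InsufficientDataError("every group needs n >= 2")
    all_vals = np.concatenate(arrs)
    grand = all_vals.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrs)
    df_between = len(arrs) - 1
    df_within = all_vals.size - len(arrs)
    if ss_within == 0.0:
        return (0.0, 1.0) if ss_between == 0.0 else (float("inf"), 0.0)
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = float(scipy.stats.f.sf(f_stat, df_between, df_within))
    return float(f_stat), p


def _pooled_t_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided pooled-variance two-sample t-test p-value."""
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return 1.0  # identical constant groups: no evidence of difference
    res = scipy.stats.ttest_ind(a, b, equal_var=True)
    p = float(res.pvalue)
    return 1.0 if math.isnan(p) else p


def bonferroni_pairwise(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> List[PairwiseComparison]:
    """All unordered pairwise pooled-t comparisons, Bonferroni-adjusted.

    Adjusted p = min(1, raw p * number of pairs).
    """
    if len(groups) < 2:
        raise InsufficientDataError("pairwise comparison needs >= 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrs):
        raise InsufficientDataError("every group needs n >= 2")
    if labels is None:
        labels = [f"group{i+1}" for i in range(len(arrs))]
    pairs = list(itertools.combinations(range(len(arrs)), 2))
    m = len(pairs)
    out = []
    for i, j in pairs:
        raw = _pooled_t_p(arrs[i], arrs[j])
        adj = min(1.0, raw * m)
        out.append(
            PairwiseComparison(
                group_a=str(labels[i]),
                group_b=str(labels[j]),
                raw_p=raw,
                adjusted_p=adj,
                significant=adj < alpha,
            )
        )
    return out


def compare_groups(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str],
    alpha: float = 0.05,
) -> GroupComparison:
    """Bundle summaries, the omnibus ANOVA, and Bonferroni pairwise tests."""
    summaries = [summarize(g) for g in groups]
    f_stat, p = one_way_anova(groups)
    pairwise = bonferroni_pairwise(groups, labels=labels, alpha=alpha)
    return GroupComparison(
        labels=tuple(str(l) for l in labels),
        means=tuple(s[0] for s in summaries),
        stds=tuple(s[1] for s in summaries),
        ns=tuple(s[2] for s in summaries),
        f_statistic=f_stat,
        p_value=p,
        pairwise=tuple(pairwise),
        alpha=alpha,
    )


def healing_report(
    fits_by_condition: Dict[str, Sequence[KineticsFit]],
    reference: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rate-constant table: one row per condition, compared to a reference.

    Columns: n, mean/std of k1 over all replicates, mean/std of k2 over
    the replicates classified biphasic (NaN when none), and raw
    pooled-t p-values of k1 (and k2 where available) against the
    reference condition. The reference row carries NaN p-values.
    """
    if reference not in fits_by_condition:
        raise InvalidInputError(f"reference condition {reference!r} not present")
    k1_ref = np.array([f.k1 for f in fits_by_condition[reference]], dtype=float)
    k2_ref = np.array(
        [f.k2 for f in fits_by_condition[reference] if f.model == "biphasic"],
        dtype=float,
    )
    rows = []
    for cond, fits in fits_by_condition.items():
        if not fits:
            raise InvalidInputError(f"condition {cond!r} has no fits")
        k1 = np.array([f.k1 for f in fits], dtype=float)
        k2 = np.array([f.k2 for f in fits if f.model == "biphasic"], dtype=float)
        k1_mean, k1_std, n = summarize(k1)
        if k2.size:
            k2_mean, k2_std, _ = summarize(k2)
        else:
            k2_mean = k2_std = math.nan
        p_k1 = (
            math.nan
            if cond == reference or k1.size < 2 or k1_ref.size < 2
            else _pooled_t_p(k1, k1_ref)
        )
        p_k2 = (
            math.nan
            if cond == reference or k2.size < 2 or k2_ref.size < 2
            else _pooled_t_p(k2, k2_ref)
        )
        rows.append(
            dict(
                condition=cond,
                n=n,
                k1_mean=k1_mean,
                k1_std=k1_std,
                k2_mean=k2_mean,
                k2_std=k2_std,
                p_vs_reference_k1=p_k1,
                p_vs_reference_k2=p_k2,
            )
        )
    return pd.DataFrame(rows)


def format_report(report: pd.DataFrame, alpha: float = 0.05) -> str:
    """Aligned plain-text rendering of a healing report.

    Monophasic conditions print "N.A." in the second-rate columns, the
    convention used for rate-constant tables in the wound-healing
    literature.
    """
    df = report.copy()
    for col in ("k1_mean", "k1_std", "k2_mean", "k2_std"):
        df[col] = df[col].map(lambda v: "N.A." if pd.isna(v) else f"{v:.2f}")
    for col in ("p_vs_reference_k1", "p_vs_reference_k2"):
        df[col] = df[col].map(
            lambda v: "-" if pd.isna(v) else (f"{v:.3g}*" if v < alpha else f"{v:.3g}")
        )
    return df.to_string(index=False)
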