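"""Cohort-level summaries and supporting statistics.

Recurrence tables over a binary sample x alteration matrix, two-gene
co-occurrence arithmetic by inclusion-exclusion, Kaplan-Meier estimation
and the log-rank test (lifelines), the exact Wilcoxon rank-sum test, and
per-gene Z-score normalization of expression matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats


def recurrence(matrix: pd.DataFrame, min_fraction: float = 0.0) -> pd.DataFrame:
    """Counts and cohort fractions per alteration event.

    ``matrix`` is binary samples x events.  ``min_fraction`` is a display
    filter (e.g. 0.10 shows only events altered in more than 10% of the
    cohort); 0 keeps everything.
    """
    if len(matrix) == 0:
        return pd.DataFrame(columns=["event", "count", "fraction"])
    counts = matrix.sum(axis=0)
    table = pd.DataFrame(
        {
            "event": counts.index,
            "count": counts.to_numpy(int),
            "fraction": counts.to_numpy(float) / len(matrix),
        }
    ).sort_values(["fraction", "event"], ascending=[False, True]).reset_index(drop=True)
    if min_fraction > 0:
        table = table[table["fraction"] > min_fraction].reset_index(drop=True)
    return table


@dataclass
class Cooccurrence:
    count_a: int
    count_b: int
    count_both: int
    n: int
    union_count: int
    union_fraction: float
    fraction_a: float
    fraction_b: float
    fraction_both: float
    jaccard: float


def cooccurrence(count_a: int, count_b: int, count_both: int, n: int) -> Cooccurrence:
    """Inclusion-exclusion arithmetic for two co-occurring alterations.

    union = A + B - both; Jaccard = both / union.
    """
    if count_both > min(count_a, count_b):
        raise ValueError("count_both exceeds a marginal count")
    if max(count_a, count_b) > n or min(count_a, count_b, count_both, n) < 0:
        raise ValueError("inconsistent counts")
    union = count_a + count_b - count_both
    return Cooccurrence(
        count_a=count_a,
        count_b=count_b,
        count_both=count_both,
        n=n,
        union_count=union,
        union_fraction=union / n,
        fraction_a=count_a / n,
        fraction_b=count_b / n,
        fraction_both=count_both / n,
        jaccard=count_both / union if union else float("nan"),
    )


def km_estimate(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier survival step function per group.

    ``records`` columns: sample, time, event, group.  Returns, per group, a
    table (time, survival) of the product-limit estimate evaluated at the
    observed times, starting from S(0) = 1.
    """
    if (records["time"] < 0).any():
        raise ValueError("negative survival times")
    out = {}
    for group, grp in records.groupby("group"):
        kmf = KaplanMeierFitter()
        kmf.fit(grp["time"], event_observed=grp["event"])
        sf = kmf.survival_function_
        out[str(group)] = pd.DataFrame(
            {"time": sf.index.to_numpy(float),
             "survival": sf.iloc[:, 0].to_numpy(float)}
        )
    return out


def logrank_test(records: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p).

    The statistic sums hypergeometric observed-minus-expected deviations
    over distinct event times; p is from the 1-df chi-square.  With no
    events at all the test is vacuous: (0, 1).
    """
    groups = records["group"].unique()
    if len(groups) != 2:
        raise ValueError("log-rank test requires exactly two groups")
    a = records[records["group"] == groups[0]]
    b = records[records["group"] == groups[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    if records["event"].sum() == 0:
        return 0.0, 1.0
    res = _ll_logrank(
        a["time"], b["time"],
        event_observed_A=a["event"], event_observed_B=b["event"],
    )
    return float(res.test_statistic), float(res.p_value)


def wilcoxon_ranksum(x: np.ndarray, y: np.ndarray, mode: str = "exact") -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``mode='exact'`` uses the exact permutation null of the rank-sum
    statistic (all C(n+m, n) group assignments); it requires tie-free data
    — with ties, midranks with the normal approximation are used and a
    warning is issued.  ``mode='normal_approx'`` applies the normal
    approximation with continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    if mode == "exact":
        pooled = np.concatenate([x, y])
        if len(np.unique(pooled)) < len(pooled):
            warnings.warn("ties present; falling back to normal approximation")
            return float(stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic",
                use_continuity=True).pvalue)
        return float(stats.mannwhitneyu(
            x, y, alternative="two-sided", method="exact").pvalue)
    if mode == "normal_approx":
        return float(stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic",
            use_continuity=True).pvalue)
    raise ValueError(f"unknown mode: {mode}")


def zscore_normalize(expression: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Per-gene Z-scores of a genes x samples expression matrix.

    Uses the sample SD (ddof=1) by default.  Constant genes yield all-zero
    rows, flagged in ``result.attrs['constant_genes']``.  A single-sample
    matrix is rejected (SD undefined).
    """
    if expression.shape[1] < 2:
        raise ValueError("need >= 2 samples per gene for Z-scores")
    mean = expression.mean(axis=1)
    sd = expression.std(axis=1, ddof=ddof)
    constant = sd == 0
    sd_safe = sd.replace(0, 1.0)
    z = expression.sub(mean, axis=0).div(sd_safe, axis=0)
    z.loc[constant] = 0.0
    z.attrs["constant_genes"] = list(expression.index[constant])
    return z
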