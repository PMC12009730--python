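"""Descriptive summaries and routine statistical comparisons.

Box-plot style summaries follow the study's reporting convention: zeros
(non-engagement) are excluded by default, and quantiles use linear
interpolation between closest order statistics. The hypothesis-test
helpers are thin contracts over standard routines (Kruskal-Wallis,
Shapiro-Wilk, Pearson, Kendall's tau) that fix the report shape; no
multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .domain_types import DomainError

__all__ = ["FactorSummary", "TestReport", "summarize", "compare_groups",
           "test_distribution", "correlate"]


@dataclass(frozen=True)
class FactorSummary:
    """Order statistics of one stratum of an exposure factor.

    ``n`` counts all supplied values, ``n_engaged`` the values retained
    after zero exclusion. All statistics are NaN for an empty retained set
    (an explicit no-data summary, never silently zero).
    """

    stratum: str
    n: int
    n_engaged: int
    mean: float
    median: float
    q1: float
    q3: float
    minimum: float
    maximum: float
    p5: float
    p95: float
    zeros_excluded: bool

    @property
    def has_data(self) -> bool:
        return self.n_engaged > 0


@dataclass(frozen=True)
class TestReport:
    """Outcome of one delegated statistical routine."""

    method: str
    statistic: float
    pvalue: float
    n: int
    detail: Mapping[str, object] = field(default_factory=dict)


def summarize(
    values: Sequence[float], exclude_zeros: bool = True, stratum: str = ""
) -> FactorSummary:
    """Summary statistics with the study's zero-exclusion convention.

    Quantiles interpolate linearly between closest order statistics
    (numpy's default rule).
    """
    arr = np.asarray(list(values), dtype=float)
    retained = arr[arr != 0] if exclude_zeros else arr
    if retained.size == 0:
        nan = float("nan")
        return FactorSummary(
            stratum=stratum, n=arr.size, n_engaged=0,
            mean=nan, median=nan, q1=nan, q3=nan, minimum=nan, maximum=nan,
            p5=nan, p95=nan, zeros_excluded=exclude_zeros,
        )
    q1, med, q3 = np.percentile(retained, [25, 50, 75])
    p5, p95 = np.percentile(retained, [5, 95])
    return FactorSummary(
        stratum=stratum, n=arr.size, n_engaged=int(retained.size),
        mean=float(retained.mean()), median=float(med),
        q1=float(q1), q3=float(q3),
        minimum=float(retained.min()), maximum=float(retained.max()),
        p5=float(p5), p95=float(p95), zeros_excluded=exclude_zeros,
    )


def compare_groups(values_by_group: Mapping[str, Sequence[float]]) -> TestReport:
    """Rank-based k-sample comparison (Kruskal-Wallis) across groups."""
    if len(values_by_group) < 2:
        raise DomainError("compare_groups requires at least 2 groups")
    groups = {k: np.asarray(list(v), dtype=float) for k, v in values_by_group.items()}
    for name, arr in groups.items():
        if arr.size == 0:
            raise DomainError(f"group {name!r} is empty")
    samples = list(groups.values())
    if all(np.array_equal(samples[0], s) for s in samples[1:]):
        # Identical groups: no rank difference by construction; scipy's
        # H statistic is 0 but warns, so report the degenerate case directly.
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.kruskal(*samples)
    return TestReport(
        method="rank-based k-sample",
        statistic=float(stat), pvalue=float(p),
        n=int(sum(a.size for a in samples)),
        detail={"groups": list(groups), "group_sizes": [int(a.size) for a in samples]},
    )


def test_distribution(values: Sequence[float], family: str) -> TestReport:
    """Shapiro-Wilk normality test of values (or their logs for lognormal)."""
    if family not in ("normal", "lognormal"):
        raise DomainError(f"family must be 'normal' or 'lognormal', got {family!r}")
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 3:
        raise DomainError(f"test_distribution requires n >= 3, got n = {arr.size}")
    if family == "lognormal":
        if np.any(arr <= 0):
            raise DomainError("lognormal family requires strictly positive values")
        arr = np.log(arr)
    if np.ptp(arr) == 0:
        return TestReport(
            method="shapiro-wilk", statistic=float("nan"), pvalue=float("nan"),
            n=int(arr.size), detail={"family": family, "degenerate": "constant values"},
        )
    stat, p = stats.shapiro(arr)
    return TestReport(
        method="shapiro-wilk", statistic=float(stat), pvalue=float(p),
        n=int(arr.size), detail={"family": family},
    )


def correlate(x: Sequence[float], y: Sequence[float], method: str = "pearson") -> TestReport:
    """Pearson or Kendall's-tau correlation with its p-value."""
    xs = np.asarray(list(x), dtype=float)
    ys = np.asarray(list(y), dtype=float)
    if xs.size != ys.size:
        raise DomainError(f"length mismatch: {xs.size} vs {ys.size}")
    if xs.size < 3:
        raise DomainError(f"correlate requires n >= 3, got n = {xs.size}")
    if method == "pearson":
        res = stats.pearsonr(xs, ys)
    elif method == "kendall":
        res = stats.kendalltau(xs, ys)
    else:
        raise DomainError(f"method must be 'pearson' or 'kendall', got {method!r}")
    return TestReport(
        method=method, statistic=float(res.statistic), pvalue=float(res.pvalue),
        n=int(xs.size),
    )
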