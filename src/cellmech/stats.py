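"""Nonparametric group comparisons and descriptive summaries.

Two-sample comparisons use the Mann-Whitney U test (two-sided; exact by
enumeration for small tie-free samples, tie-corrected normal approximation
otherwise), three or more groups the Kruskal-Wallis H test.  Both are
backed by scipy.stats.  Descriptive summaries report mean, median, SD
(n-1 denominator) and the 25%/75% percentiles under linear interpolation —
the boxplot convention used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupStats",
    "GroupComparison",
    "mann_whitney",
    "kruskal_wallis",
    "summarize",
    "significance_stars",
    "percent_change",
    "holm_correction",
]

# p-value star convention: ns p>0.05, * p<0.05, ** p<0.01, *** p<0.001
_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))

EXACT_MAX_TOTAL = 14  # exact enumeration when n_a + n_b <= this and no ties


@dataclass(frozen=True)
class GroupStats:
    """Five-descriptor summary of one sample (boxplot statistics)."""

    label: str
    n: int
    mean: float
    median: float
    sd: float
    p25: float
    p75: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.p25 <= self.median <= self.p75:
            raise ValueError("percentiles must satisfy p25 <= median <= p75")


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample Mann-Whitney result with an effect summary."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    u_statistic: float  # smaller of U_a, U_b
    p_value: float
    percent_change: float  # of means, b relative to a, in %
    stars: str
    method: str  # "exact" or "normal"

    def __post_init__(self) -> None:
        if not 0 <= self.u_statistic <= self.n_a * self.n_b:
            raise ValueError("U must lie in [0, n_a*n_b]")
        if not 0 < self.p_value <= 1:
            raise ValueError("p must lie in (0, 1]")


def significance_stars(p: float) -> str:
    for level, stars in _STAR_LEVELS:
        if p < level:
            return stars
    return "ns"


def percent_change(a: Sequence[float], b: Sequence[float]) -> float:
    """Percent change of the mean of ``b`` relative to the mean of ``a``."""
    mean_a = float(np.mean(a))
    mean_b = float(np.mean(b))
    if mean_a == 0:
        raise ValueError("mean of the reference sample is zero")
    return 100.0 * (mean_b - mean_a) / mean_a


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    mode: str = "auto",
    label_a: str = "a",
    label_b: str = "b",
) -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    ``mode="auto"`` uses the exact null distribution when
    ``n_a + n_b <= 14`` and the pooled sample is tie-free, otherwise the
    tie-corrected normal approximation (with continuity correction).  The
    reported U is the smaller of U_a and U_b, the convention of classical
    tables.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "auto":
        mode = (
            "exact"
            if (a.size + b.size <= EXACT_MAX_TOTAL and not _has_ties(a, b))
            else "normal"
        )
    if mode == "exact" and _has_ties(a, b):
        raise ValueError("exact mode requires a tie-free pooled sample")
    method = "exact" if mode == "exact" else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u_a = float(res.statistic)
    u = min(u_a, a.size * b.size - u_a)
    p = min(float(res.pvalue), 1.0)
    return GroupComparison(
        label_a=label_a,
        label_b=label_b,
        n_a=int(a.size),
        n_b=int(b.size),
        u_statistic=u,
        p_value=p,
        percent_change=percent_change(a, b),
        stars=significance_stars(p),
        method="exact" if mode == "exact" else "normal",
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p (k-1 df)."""
    if len(groups) < 3:
        raise ValueError(
            "kruskal_wallis needs >= 3 groups; use mann_whitney for two"
        )
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0  # scipy rejects all-identical input; H is 0 by definition
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def summarize(sample: Sequence[float], label: str = "") -> GroupStats:
    """Mean, median, SD (ddof=1; 0 for a single value), p25/p75 (linear)."""
    x = np.asarray(sample, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return GroupStats(
        label=label,
        n=int(x.size),
        mean=float(np.mean(x)),
        median=float(np.median(x)),
        sd=sd,
        p25=float(np.percentile(x, 25)),
        p75=float(np.percentile(x, 75)),
    )


def holm_correction(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values (off by default in the pipeline)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()
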