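"""Shared statistical primitives.

Pure in-memory routines used by both analysis arms: pooled-variance
t-test, one-way ANOVA, Tukey HSD (Tukey-Kramer for unbalanced designs),
Benjamini-Hochberg FDR, Pearson/Spearman correlation and correlation-
distance hierarchical clustering. Every routine is deliberately simple
enough to check against a brute-force oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform

__all__ = [
    "TestResult",
    "FDRResult",
    "student_t_test",
    "one_way_anova",
    "tukey_hsd",
    "tukey_critical_value",
    "bh_fdr",
    "correlation",
    "hier_cluster",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided hypothesis test."""

    statistic: float
    df: tuple[float, ...]
    pvalue: float
    note: str = ""


@dataclass(frozen=True)
class FDRResult:
    """Benjamini-Hochberg adjusted p-values with significance flags."""

    qvalues: np.ndarray
    significant: np.ndarray
    alpha: float = 0.05


@dataclass(frozen=True)
class TukeyPair:
    """One pairwise comparison from a Tukey HSD table."""

    group_a: object
    group_b: object
    diff: float
    pvalue: float


def _as_clean_array(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    return arr[~np.isnan(arr)]


def student_t_test(x, y) -> TestResult:
    """Two-sided pooled-variance (Student's) two-sample t-test.

    By convention, zero pooled variance with equal means yields ``p = 1``
    (statistic 0); zero pooled variance with unequal means yields ``p = 0``.
    """
    x = _as_clean_array(x)
    y = _as_clean_array(y)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError(f"need >= 2 values per sample, got {nx} and {ny}")
    df = nx + ny - 2
    pooled_var = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / df
    diff = np.mean(x) - np.mean(y)
    if pooled_var == 0.0:
        if diff == 0.0:
            return TestResult(0.0, (float(df),), 1.0, note="zero pooled variance, equal means")
        return TestResult(np.inf if diff > 0 else -np.inf, (float(df),), 0.0,
                          note="zero pooled variance, unequal means")
    t = diff / np.sqrt(pooled_var * (1.0 / nx + 1.0 / ny))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), (float(df),), float(min(p, 1.0)))


def one_way_anova(groups) -> TestResult:
    """One-way fixed-effects ANOVA over >= 2 groups of >= 2 values each."""
    arrays = [_as_clean_array(g) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(arrays):
        if len(g) < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    k = len(arrays)
    n_total = sum(len(g) for g in arrays)
    grand = np.mean(np.concatenate(arrays))
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in arrays)
    ss_within = sum(np.sum((g - np.mean(g)) ** 2) for g in arrays)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0.0 and ss_between == 0.0:
        return TestResult(0.0, (float(df_b), float(df_w)), 1.0,
                          note="zero variance everywhere")
    if ss_within == 0.0:
        return TestResult(np.inf, (float(df_b), float(df_w)), 0.0,
                          note="zero within-group variance")
    f = (ss_between / df_b) / (ss_within / df_w)
    p = sps.f.sf(f, df_b, df_w)
    return TestResult(float(f), (float(df_b), float(df_w)), float(p))


def tukey_hsd(groups, labels=None) -> list[TukeyPair]:
    """All-pairs Tukey HSD adjusted p-values.

    Unbalanced designs use the Tukey-Kramer statistic
    ``|m_i - m_j| / sqrt(MSW * (1/n_i + 1/n_j) / 2)`` referred to the
    studentized range distribution with ``k`` groups and the ANOVA
    within-group degrees of freedom.
    """
    arrays = [_as_clean_array(g) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(arrays):
        if len(g) < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    if labels is None:
        labels = list(range(len(arrays)))
    k = len(arrays)
    df_w = sum(len(g) for g in arrays) - k
    msw = sum(np.sum((g - np.mean(g)) ** 2) for g in arrays) / df_w
    out: list[TukeyPair] = []
    for i, j in itertools.combinations(range(k), 2):
        diff = float(np.mean(arrays[i]) - np.mean(arrays[j]))
        if msw == 0.0:
            p = 1.0 if diff == 0.0 else 0.0
        else:
            se = np.sqrt(msw * (1.0 / len(arrays[i]) + 1.0 / len(arrays[j])) / 2.0)
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df_w))
        out.append(TukeyPair(labels[i], labels[j], diff, float(min(max(p, 0.0), 1.0))))
    return out


def tukey_critical_value(alpha: float, k: int, df: int) -> float:
    """Critical value of the studentized range at tail probability alpha."""
    return float(sps.studentized_range.isf(alpha, k, df))


def bh_fdr(pvals, alpha: float = 0.05) -> FDRResult:
    """Benjamini-Hochberg step-up q-values with enforced monotonicity.

    NaN p-values get NaN q-values and are never flagged; they do not count
    toward the number of tests.
    """
    p = np.asarray(pvals, dtype=float).ravel()
    q = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    if pv.size:
        if np.any((pv < 0) | (pv > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        m = pv.size
        order = np.argsort(pv, kind="stable")
        ranked = pv[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        qv = np.empty(m)
        qv[order] = np.minimum(ranked, 1.0)
        q[valid] = qv
    significant = np.zeros(p.shape, dtype=bool)
    significant[valid] = q[valid] <= alpha
    return FDRResult(qvalues=q, significant=significant, alpha=alpha)


def correlation(x, y, method: str = "pearson") -> float:
    """Pearson or Spearman correlation; NaN if either vector is constant.

    Spearman uses average (fractional) ranks for ties.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if method == "spearman":
        x = sps.rankdata(x)
        y = sps.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    sx = np.std(x)
    sy = np.std(y)
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    r = float(np.mean((x - np.mean(x)) * (y - np.mean(y))) / (sx * sy))
    return max(-1.0, min(1.0, r))


def correlation_distance_matrix(rows: np.ndarray, method: str = "pearson") -> np.ndarray:
    """Pairwise ``1 - correlation`` distances between matrix rows.

    Rows with zero variance have undefined correlation; their distance to
    every other row is set to 1 (correlation treated as 0).
    """
    rows = np.asarray(rows, dtype=float)
    n = rows.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = correlation(rows[i], rows[j], method=method)
            d = 1.0 if np.isnan(r) else 1.0 - r
            dist[i, j] = dist[j, i] = d
    return dist


def hier_cluster(rows, method: str = "spearman", k: int = 2) -> np.ndarray:
    """Average-linkage clustering of rows with 1 - correlation distance.

    Returns integer labels ``0..k-1``. The tree is always cut into exactly
    ``k`` clusters (ties broken by merge order, deterministic for a fixed
    input order), so degenerate all-identical inputs still yield ``k``
    groups, split at zero height.
    """
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2:
        raise ValueError("rows must be a 2-D array")
    if rows.shape[0] < k:
        raise ValueError(f"need at least k={k} rows, got {rows.shape[0]}")
    if rows.shape[0] == k:
        return np.arange(k)
    dist = correlation_distance_matrix(rows, method=method)
    z = sch.linkage(squareform(dist, checks=False), method="average")
    labels = sch.cut_tree(z, n_clusters=k).ravel()
    return labels.astype(int)
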