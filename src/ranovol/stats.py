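"""Nonparametric cohort statistics: median/IQR summaries, paired and
two-sample rank tests, and rank correlation.

The conventions follow the analysis they reproduce: two-sided tests at
alpha = 0.05, medians with interquartile ranges by linear interpolation
between order statistics, signed-rank tests with zero differences
dropped, and Spearman correlation pooled over all lesion-timepoint
pairs.  Exact small-sample null distributions are used where feasible
(signed-rank n <= 25, rank-sum min(n) <= 8 without ties, Spearman
n <= 10 by full permutation enumeration).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "WindowSummary", "TestResult", "window_summary", "paired_signed_rank",
    "two_sample_rank", "rank_correlation", "stratified_summaries",
]

ALPHA = 0.05


@dataclass(frozen=True)
class WindowSummary:
    window: Optional[str]
    n: int
    median: float
    q1: float
    q3: float


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: Tuple[int, ...]
    method: str
    alpha: float = ALPHA
    degenerate: bool = False
    rho: Optional[float] = None


def window_summary(values: Sequence[float],
                   window: Optional[str] = None) -> WindowSummary:
    """Median and interquartile range of the non-absent values.

    Quartiles interpolate linearly between order statistics.  Raises on
    empty input.
    """
    arr = np.asarray([v for v in values if v is not None and not np.isnan(v)],
                     dtype=float)
    if arr.size == 0:
        raise ValueError("window summary undefined for empty input")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return WindowSummary(window=window, n=int(arr.size), median=float(med),
                         q1=float(q1), q3=float(q3))


def paired_signed_rank(pre: Sequence[float],
                       post: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on aligned pairs.

    Zero differences are dropped (changing the effective n, which is
    reported).  The exact null distribution is used for n <= 25 with
    untied absolute differences, the normal approximation with tie
    correction otherwise.  All-zero differences are degenerate: p = 1.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be aligned, equal-length vectors")
    d = post - pre
    d = d[d != 0]
    n = int(d.size)
    if n == 0:
        return TestResult(statistic=0.0, p_value=1.0, n=(0,),
                          method="signed-rank (degenerate)", degenerate=True)
    exact = n <= 25 and np.unique(np.abs(d)).size == n
    res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                       method="exact" if exact else "approx")
    return TestResult(statistic=float(res.statistic),
                      p_value=float(min(res.pvalue, 1.0)), n=(n,),
                      method="signed-rank exact" if exact
                      else "signed-rank normal approx")


def two_sample_rank(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-tailed Mann-Whitney U test.

    Exact for min(len) <= 8 without ties across the pooled sample,
    asymptotic with continuity and tie correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    exact = (min(a.size, b.size) <= 8
             and np.unique(pooled).size == pooled.size)
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    return TestResult(statistic=float(res.statistic),
                      p_value=float(min(res.pvalue, 1.0)),
                      n=(int(a.size), int(b.size)),
                      method="rank-sum exact" if exact
                      else "rank-sum asymptotic")


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum())
    return float((rxc * ryc).sum() / denom)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray,
                      rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho: enumerate all
    pairings of one rank vector against the other, in vectorised chunks."""
    n = rx.size
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum())
    total = 0
    hits = 0
    thresh = abs(rho_obs) - 1e-12
    chunk = []
    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == 100_000:
            rhos = (ryc[np.array(chunk)] @ rxc) / denom
            hits += int((np.abs(rhos) >= thresh).sum())
            total += len(chunk)
            chunk = []
    if chunk:
        rhos = (ryc[np.array(chunk)] @ rxc) / denom
        hits += int((np.abs(rhos) >= thresh).sum())
        total += len(chunk)
    return hits / total


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation with average ranks for ties.

    p-value from full permutation enumeration for n <= 10, from the
    t-approximation for larger n.  Constant input on either axis leaves
    rho undefined (NaN, degenerate flag set).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be the same length")
    n = int(x.size)
    if n < 3:
        raise ValueError("rank correlation needs at least 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return TestResult(statistic=np.nan, p_value=np.nan, n=(n,),
                          method="spearman (constant axis)",
                          degenerate=True, rho=np.nan)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _spearman_rho(rx, ry)
    if n <= 10:
        p = _exact_spearman_p(rx, ry, rho)
        method = "spearman exact permutation"
    else:
        res = sps.spearmanr(x, y)
        p = float(res.pvalue)
        method = "spearman t-approximation"
    return TestResult(statistic=rho, p_value=float(min(p, 1.0)), n=(n,),
                      method=method, rho=rho)


def stratified_summaries(df: pd.DataFrame, value_col: str, group_col: str,
                         window_col: Optional[str] = None) -> pd.DataFrame:
    """Descriptive per-group summaries with rank-sum comparisons.

    One row per (window x) group with n / median / IQR; when a stratum
    has exactly two non-empty groups, a two-tailed rank-sum comparison
    between them is attached to both rows (column ``p_value``).
    Purely descriptive: no causal claim is implied by a steroid or
    vital-status grouping.
    """
    rows = []
    strata = (df.groupby(window_col, sort=True) if window_col
              else [(None, df)])
    for wname, wdf in strata:
        groups = {}
        for gname, gdf in wdf.groupby(group_col, sort=True, dropna=False):
            vals = gdf[value_col].dropna().to_numpy()
            if vals.size:
                groups[gname] = vals
        p = None
        if len(groups) == 2:
            a, b = groups.values()
            p = two_sample_rank(a, b).p_value
        for gname, vals in groups.items():
            s = window_summary(vals)
            rows.append({"window": wname, "group": gname, "n": s.n,
                         "median": s.median, "q1": s.q1, "q3": s.q3,
                         "p_value": p})
    return pd.DataFrame(rows,
                        columns=["window", "group", "n", "median", "q1",
                                 "q3", "p_value"])
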