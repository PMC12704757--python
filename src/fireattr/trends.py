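"""Robust trend statistics: Theil–Sen slope and the Mann–Kendall test.

The Theil–Sen estimator (median of all pairwise slopes) is delegated to
:func:`scipy.stats.theilslopes`; the Mann–Kendall S statistic, its exact
small-sample null distribution and the tie-corrected normal approximation are
implemented here. Slopes on annual burned-area series are additionally
reported in units of the series' own standard deviation per decade
(sigma/decade), the convention used for cross-region comparison.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TrendResult", "mann_kendall_s", "mann_kendall_pvalue", "theil_sen_trend"]

#: series length at or below which the exact Mann–Kendall null distribution is used
EXACT_N_MAX = 10


@dataclass(frozen=True)
class TrendResult:
    """Trend of an annual series.

    Attributes
    ----------
    slope : float
        Theil–Sen slope in native units per year.
    slope_sigma_per_decade : float
        ``10 * slope / std(series)``; NaN (flagged) for a constant series.
    mk_s : int
        Mann–Kendall S statistic, the sum of pairwise signs.
    p_value : float
        Two-sided p-value of the monotone-trend null.
    significant : bool
        ``p_value < alpha``.
    alpha : float
        Significance level used.
    flags : tuple of str
        Diagnostic flags ("constant_series", "exact_p", "ties_present").
    """

    slope: float
    slope_sigma_per_decade: float
    mk_s: int
    p_value: float
    significant: bool
    alpha: float = 0.05
    intercept: float = float("nan")
    flags: tuple = field(default_factory=tuple)


def mann_kendall_s(y: np.ndarray) -> int:
    """S = sum over i<j of sign(y_j - y_i)."""
    y = np.asarray(y, dtype=float)
    diff = np.sign(y[None, :] - y[:, None])
    return int(np.triu(diff, k=1).sum())


@lru_cache(maxsize=32)
def _s_distribution(n: int) -> dict:
    """Exact null distribution of S for tie-free series of length n.

    Counts permutations by number of inversions d via the classical DP;
    S = n(n-1)/2 - 2d.
    """
    # c[d] = number of permutations of {1..m} with d inversions
    c = np.array([1.0])
    for m in range(2, n + 1):
        new = np.zeros(len(c) + m - 1)
        for k in range(m):
            new[k : k + len(c)] += c
        c = new
    total = c.sum()
    nmax = n * (n - 1) // 2
    return {nmax - 2 * d: c[d] / total for d in range(len(c))}


def mann_kendall_pvalue(y: np.ndarray) -> tuple[float, list[str]]:
    """Two-sided p-value for the Mann–Kendall S statistic.

    Exact enumeration for n <= EXACT_N_MAX without ties; tie-corrected normal
    approximation with continuity correction otherwise.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    s = mann_kendall_s(y)
    _, counts = np.unique(y, return_counts=True)
    has_ties = bool((counts > 1).any())
    flags: list[str] = []
    if has_ties:
        flags.append("ties_present")
    if n <= EXACT_N_MAX and not has_ties:
        dist = _s_distribution(n)
        p = float(sum(prob for sv, prob in dist.items() if abs(sv) >= abs(s)))
        flags.append("exact_p")
        return min(p, 1.0), flags
    var = (n * (n - 1) * (2 * n + 5) - np.sum(counts * (counts - 1) * (2 * counts + 5))) / 18.0
    if var <= 0:
        return 1.0, flags + ["zero_variance"]
    if s > 0:
        z = (s - 1) / np.sqrt(var)
    elif s < 0:
        z = (s + 1) / np.sqrt(var)
    else:
        z = 0.0
    p = float(2 * stats.norm.sf(abs(z)))
    return min(p, 1.0), flags


def theil_sen_trend(series, years=None, alpha: float = 0.05) -> TrendResult:
    """Theil–Sen slope with Mann–Kendall significance for an annual series.

    Parameters
    ----------
    series : array-like or pandas.Series
        Annual values; if a pandas Series, its index supplies the years.
    years : array-like, optional
        Time axis; defaults to the Series index or 0..n-1.
    alpha : float
        Significance level for the Mann–Kendall test.
    """
    if years is None and isinstance(series, pd.Series):
        years = np.asarray(series.index, dtype=float)
    y = np.asarray(series, dtype=float)
    if years is None:
        years = np.arange(len(y), dtype=float)
    years = np.asarray(years, dtype=float)
    if len(y) < 3:
        raise ValueError("trend requires a series of length >= 3")
    flags: list[str] = []
    sigma = float(np.std(y))
    if np.allclose(y, y[0]):
        p, pflags = mann_kendall_pvalue(y)
        return TrendResult(
            slope=0.0,
            slope_sigma_per_decade=float("nan"),
            mk_s=0,
            p_value=p,
            significant=False,
            alpha=alpha,
            intercept=float(y[0]),
            flags=tuple(["constant_series"] + pflags),
        )
    ts = stats.theilslopes(y, years)
    p, pflags = mann_kendall_pvalue(y)
    flags += pflags
    s = mann_kendall_s(y)
    return TrendResult(
        slope=float(ts.slope),
        slope_sigma_per_decade=10.0 * float(ts.slope) / sigma,
        mk_s=s,
        p_value=p,
        significant=bool(p < alpha),
        alpha=alpha,
        intercept=float(ts.intercept),
        flags=tuple(flags),
    )
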