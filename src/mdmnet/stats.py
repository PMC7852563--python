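"""Shared statistical primitives: rank-sum test, Holm adjustment, t-test.

The Wilcoxon rank-sum (Mann-Whitney) test used throughout the network
comparisons switches between an exact two-sided p value (computed by
enumeration of group assignments, valid with ties) for small groups and
a tie-corrected normal approximation with continuity correction
otherwise.  The two-sided exact convention is "double the smaller tail",
capped at 1.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, sqrt

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["rank_sum_test", "holm_adjust", "welch_ttest"]

#: largest per-group size for which the exact rank-sum null is enumerated
EXACT_MAX = 8


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x over y, with half-counts for ties."""
    diff = x[:, None] - y[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def rank_sum_test(
    x, y, *, exact_max: int = EXACT_MAX
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns ``(U, p)``.

    With both groups of size <= ``exact_max`` the null distribution of U
    is enumerated exactly over all assignments of the pooled values
    (conditional on the observed values, so ties are handled exactly);
    otherwise a tie-corrected normal approximation with continuity
    correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    u = _u_statistic(x, y)
    n, m = x.size, y.size
    if n <= exact_max and m <= exact_max:
        pooled = np.concatenate([x, y])
        total = comb(n + m, n)
        le = ge = 0
        for idx in combinations(range(n + m), n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(idx)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            if u_perm <= u + 1e-12:
                le += 1
            if u_perm >= u - 1e-12:
                ge += 1
        p = min(1.0, 2.0 * min(le / total, ge / total))
        return u, p
    mean = n * m / 2.0
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    big_n = n + m
    tie_term = ((counts**3 - counts).sum()) / (big_n * (big_n - 1))
    var = n * m / 12.0 * (big_n + 1 - tie_term)
    if var <= 0:
        return u, 1.0
    # continuity correction toward the mean
    z = (u - mean - 0.5 * np.sign(u - mean)) / sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return u, float(p)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p values; NaNs are passed through."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="holm")[1]
    return out


def welch_ttest(a, b, *, equal_var: bool = False) -> tuple[float, float]:
    """Two-sample two-sided t-test (Welch by default); returns ``(t, p)``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least two values")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if np.isnan(p):  # both groups constant and equal
        return 0.0, 1.0
    return float(t), float(p)
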