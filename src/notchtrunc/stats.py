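"""Shared statistical primitives: rank-sum test and multiple-testing control.

The rank-sum test uses exhaustive permutation enumeration for small groups
(exact even under ties) and a tie-corrected normal approximation for larger
ones. Benjamini-Hochberg and Bonferroni adjustments are implemented directly
so they can be validated against brute-force oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

__all__ = [
    "RankSumResult",
    "rank_sum_test",
    "benjamini_hochberg",
    "bonferroni",
]

# above this many subsets the exact path is abandoned for the normal
# approximation; C(50, 25) style cases are never enumerated
_EXACT_SUBSET_LIMIT = 200_000


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank sum of the first group (midranks)
    pvalue: float
    method: str  # "exact" | "asymptotic"


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def rank_sum_test(x, y) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact permutation p-value when the number of group assignments is small
    enough to enumerate; otherwise normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("rank_sum_test requires two non-empty groups")
    pooled = np.concatenate([x, y])
    n = n1 + n2
    ranks = _midranks(pooled)
    w = float(ranks[:n1].sum())
    mu = n1 * (n + 1) / 2.0

    if comb(n, n1) <= _EXACT_SUBSET_LIMIT:
        obs = abs(w - mu)
        hits = 0
        total = 0
        for idx in combinations(range(n), n1):
            total += 1
            if abs(ranks[list(idx)].sum() - mu) >= obs - 1e-9:
                hits += 1
        return RankSumResult(w, hits / total, "exact")

    # tie-corrected variance of the rank sum
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all values identical
        return RankSumResult(w, 1.0, "asymptotic")
    z = (w - mu) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return RankSumResult(w, min(1.0, float(p)), "asymptotic")


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjusted p-values (monotone q-values, clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


def bonferroni(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    return np.clip(p * p.size, 0.0, 1.0)
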