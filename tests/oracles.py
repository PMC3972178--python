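"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: rank-sum
p-values by full enumeration of rank assignments, BH by literal step-up,
hypergeometric tails by direct summation of point probabilities.
"""

from itertools import combinations
from math import comb

import numpy as np
from scipy import stats


def enum_ranksum_p(a, b, alternative: str) -> float:
    """Exact rank-sum p-value by enumerating all C(n1+n2, n1) assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * len(b) / 2
    us = np.array(
        [
            ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
            for idx in combinations(range(len(pooled)), n1)
        ]
    )
    if alternative == "greater":
        return float((us >= u_obs).mean())
    if alternative == "less":
        return float((us <= u_obs).mean())
    return float((np.abs(us - mu) >= abs(u_obs - mu)).mean())


def stepup_bh(p: np.ndarray) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up, written longhand."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * n / rank_from_top)
        adjusted[idx] = running_min
    return adjusted


def hypergeom_upper_tail(k: int, total: int, successes: int, drawn: int) -> float:
    """P(X >= k) for X ~ Hypergeometric, by direct summation."""
    denom = comb(total, drawn)
    upper = min(successes, drawn)
    return sum(
        comb(successes, x) * comb(total - successes, drawn - x) for x in range(k, upper + 1)
    ) / denom


def fisher_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Point-probability two-tailed Fisher p by summing the support."""
    row1, col1, total = a + b, a + c, a + b + c + d
    denom = comb(total, row1)

    def point(x: int) -> float:
        return comb(col1, x) * comb(total - col1, row1 - x) / denom

    p_obs = point(a)
    lo, hi = max(0, row1 + col1 - total), min(row1, col1)
    return sum(point(x) for x in range(lo, hi + 1) if point(x) <= p_obs * (1 + 1e-7))
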