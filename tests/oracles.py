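"""Independent brute-force oracles the implementation is checked against.

Deliberately written with different algorithms/representations than the
package code: exact rational arithmetic for the HWE enumeration, a literal
textbook loop for the BH step-up, and exhaustive split enumeration for the
cutoff search.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def hwe_enum_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact-rational enumeration of the conditional HWE test.

    Counts arrangements for every heterozygote count with the right parity:
    ways(h) = n! / (homr! h! homc!) * 2^h; p is the normalized mass of
    outcomes no more likely than the observed one (integer comparison, so no
    floating tolerance is involved).
    """
    n = n_AA + n_Aa + n_aa
    rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if rare == 0:
        return 1.0
    ways = {}
    for h in range(rare % 2, rare + 1, 2):
        homr = (rare - h) // 2
        homc = n - h - homr
        if homr < 0 or homc < 0:
            continue
        ways[h] = (
            math.factorial(n)
            // (math.factorial(homr) * math.factorial(h) * math.factorial(homc))
            * 2**h
        )
    total = sum(ways.values())
    obs = ways[n_Aa]
    p = Fraction(sum(w for w in ways.values() if w <= obs), total)
    return float(p)


def bh_stepup(p_values) -> list[float]:
    """Literal textbook Benjamini-Hochberg: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(order, start=1):
        candidates = []
        for later_pos in range(rank_pos, m + 1):
            j = order[later_pos - 1]
            candidates.append(p[j] * m / later_pos)
        q[i] = min(1.0, min(candidates))
    return q


def cutoff_bruteforce(scores, delta_bfm, min_class_size, criterion="mean_diff"):
    """Exhaustive enumeration of all valid midpoint splits.

    Returns (cutoff, objective). Tie-break: nearest to the score median,
    then the smaller cutoff.
    """
    from scipy import stats

    s = np.asarray(scores, dtype=float)
    y = np.asarray(delta_bfm, dtype=float)
    distinct = sorted(set(s.tolist()))
    median = float(np.median(s))
    best = None
    for a, b in zip(distinct[:-1], distinct[1:]):
        cut = (a + b) / 2.0
        hi = s > cut
        if hi.sum() < min_class_size or (~hi).sum() < min_class_size:
            continue
        if criterion == "mean_diff":
            obj = abs(y[hi].mean() - y[~hi].mean())
        else:
            obj = abs(stats.ttest_ind(y[hi], y[~hi], equal_var=False).statistic)
        if not np.isfinite(obj):
            obj = 0.0
        if best is None:
            best = (obj, cut)
            continue
        if obj > best[0] + 1e-12:
            best = (obj, cut)
        elif abs(obj - best[0]) <= 1e-12:
            if abs(cut - median) < abs(best[1] - median) - 1e-12:
                best = (obj, cut)
            elif (
                abs(abs(cut - median) - abs(best[1] - median)) <= 1e-12
                and cut < best[1]
            ):
                best = (obj, cut)
    if best is None:
        raise ValueError("no valid split")
    return best[1], best[0]


def ols_normal_equations(X, y):
    """OLS coefficients by explicit normal-equations inversion."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.linalg.inv(X.T @ X) @ (X.T @ y)
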