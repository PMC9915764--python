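"""Brute-force reference implementations used only to check the package.

Everything here is deliberately naive — direct enumeration or O(n^2)
pairwise computation — and independent of the code paths under test.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


def bh_bruteforce(p):
    """BH adjusted p-values by the defining min-over-tail formula."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def hypergeom_tail_bruteforce(a, n_universe, n_set, n_draw):
    """P(X >= a) for a hypergeometric overlap, by exact summation."""
    total = Fraction(0)
    denom = comb(n_universe, n_draw)
    for k in range(a, min(n_set, n_draw) + 1):
        total += Fraction(comb(n_set, k) * comb(n_universe - n_set,
                                                n_draw - k), denom)
    return float(total)


def fisher_two_sided_bruteforce(a, b, c, d):
    """Two-sided Fisher exact p by enumerating tables with fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs:
            total += px
    return float(total)


def auroc_bruteforce(member_stats, other_stats):
    """AUROC by exhaustive pairwise comparison (distinct values assumed)."""
    wins = sum(1 for m in member_stats for o in other_stats if m > o)
    return wins / (len(member_stats) * len(other_stats))


def overlap_bruteforce(list_a, list_b, i, j):
    """|top-i of A intersect top-j of B| by direct set construction."""
    return len(set(list_a[:i]) & set(list_b[:j]))
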