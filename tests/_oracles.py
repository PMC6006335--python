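"""Independent brute-force oracles used by the statistical tests.

These deliberately avoid the code paths they check: the Mann-Whitney oracle
enumerates every assignment of the pooled observations to the two groups;
the Fisher oracle sums the hypergeometric mass of all tables at least as
extreme as the observed one; the BH oracle is the textbook sort-based
step-up definition.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.stats import hypergeom, rankdata


def mw_enum_p(x, y) -> float:
    """Two-sided Mann-Whitney p by exhaustive rank-assignment enumeration."""
    x = list(x)
    y = list(y)
    pooled = np.asarray(x + y, dtype=float)
    n = len(x)
    ranks = rankdata(pooled)
    obs = ranks[:n].sum() - n * (n + 1) / 2
    us = np.array([
        sum(ranks[i] for i in idx) - n * (n + 1) / 2
        for idx in combinations(range(len(pooled)), n)
    ])
    eps = 1e-9
    lo = (us <= obs + eps).mean()
    hi = (us >= obs - eps).mean()
    return min(1.0, 2.0 * min(lo, hi))


def fisher_enum_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by direct summation over the 2x2 margin."""
    n_total = a + b + c + d
    k_col = a + c
    n_row = a + b
    rv = hypergeom(n_total, k_col, n_row)
    p_obs = rv.pmf(a)
    lo = max(0, n_row - (n_total - k_col))
    hi = min(k_col, n_row)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = rv.pmf(k)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(1.0, total)


def bh_sort_based(p) -> np.ndarray:
    """BH adjusted p-values from the sorted step-up definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
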