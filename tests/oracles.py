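"""Independent brute-force reference implementations used only by tests.

Everything here is written as a direct, loop-based transcription of the
defining formulas, deliberately sharing no code with the package so that
agreement is evidence rather than tautology.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def o_entropy(p, normalized=False):
    h = 0.0
    for pi in p:
        if pi > 0:
            h -= pi * math.log2(pi)
    if normalized:
        h /= math.log2(len(p))
    return h


def o_laplace(x, normalized=False):
    n = len(x)
    total = sum(x) + n
    q = [(xi + 1.0) / total for xi in x]
    return o_entropy(q, normalized=normalized)


def o_gini(p):
    n = len(p)
    pair = 0.0
    for pi in p:
        for pj in p:
            pair += abs(pi - pj)
    pbar = 1.0 / n
    return pair / (2.0 * n * n * pbar) * n / (n - 1)


def o_simpson(p):
    return 1.0 - sum(pi * pi for pi in p)


def o_invsimpson(p):
    return 1.0 / sum(pi * pi for pi in p)


def o_mad(values):
    values = sorted(values)
    med = _median(values)
    return _median(sorted(abs(v - med) for v in values))


def _median(sorted_vals):
    n = len(sorted_vals)
    mid = n // 2
    if n % 2:
        return sorted_vals[mid]
    return 0.5 * (sorted_vals[mid - 1] + sorted_vals[mid])


def o_bh(pvals):
    """Step-up BH on a list without NaN."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [None] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(pvals[i] * m / rank_from_top, 1.0)
        running_min = min(running_min, val)
        adjusted[i] = running_min
    return adjusted


def o_perm_pvalue(v1, v2, central="mean"):
    """Exact permutation p-value of |difference of centrals| by full
    enumeration of group-1 position assignments."""
    pooled = list(v1) + list(v2)
    n, n1 = len(pooled), len(v1)

    def cent(vals):
        return float(np.mean(vals)) if central == "mean" else float(np.median(vals))

    obs = abs(cent(v1) - cent(v2))
    hits = total = 0
    for idx in combinations(range(n), n1):
        g1 = [pooled[i] for i in idx]
        g2 = [pooled[i] for i in range(n) if i not in idx]
        if abs(cent(g1) - cent(g2)) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def o_mwu_exact_pvalue(a, b):
    """Exact two-sided Mann-Whitney p-value for tie-free samples, by full
    enumeration of which pooled positions belong to the first group."""
    pooled = list(a) + list(b)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    n, n1 = len(pooled), len(a)
    n2 = n - n1
    mu = n1 * n2 / 2.0

    def u_stat(g1, g2):
        return sum(1 for x in g1 for y in g2 if x > y)

    obs = abs(u_stat(a, b) - mu)
    hits = total = 0
    for idx in combinations(range(n), n1):
        g1 = [pooled[i] for i in idx]
        g2 = [pooled[i] for i in range(n) if i not in idx]
        if abs(u_stat(g1, g2) - mu) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def compositions_of_tenths(n):
    """All vectors of non-negative tenths summing to 1 with n parts."""
    out = []

    def rec(prefix, remaining, parts):
        if parts == 1:
            out.append(prefix + [remaining])
            return
        for k in range(remaining + 1):
            rec(prefix + [k], remaining - k, parts - 1)

    rec([], 10, n)
    return [[k / 10.0 for k in comp] for comp in out]
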