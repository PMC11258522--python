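"""Independent brute-force oracles used by the tests.

Every function here is a deliberately naive nested-loop (or full
enumeration) implementation, kept independent of the package's vectorised
code paths so the two can be compared.
"""

import itertools
import math

import numpy as np


def is_bruteforce(days: np.ndarray) -> float:
    """Interdaily stability by direct loops over a (D, 24) matrix."""
    d, p = days.shape
    n = d * p
    flat = [days[i][h] for i in range(d) for h in range(p)]
    grand = sum(flat) / n
    num = 0.0
    for h in range(p):
        tmpl = sum(days[i][h] for i in range(d)) / d
        num += (tmpl - grand) ** 2
    den = sum((x - grand) ** 2 for x in flat)
    return (n * num) / (p * den)


def iv_bruteforce(days: np.ndarray) -> float:
    """Intradaily variability by direct loops over a (D, 24) matrix."""
    flat = [v for row in days for v in row]
    n = len(flat)
    grand = sum(flat) / n
    num = sum((flat[i] - flat[i - 1]) ** 2 for i in range(1, n))
    den = sum((x - grand) ** 2 for x in flat)
    return (n * num) / ((n - 1) * den)


def m10_l5_bruteforce(day: np.ndarray) -> tuple[float, int, float, int]:
    """Exhaustive within-day window scan: (m10, m10_onset, l5, l5_onset)."""
    best_m, best_mi = -math.inf, -1
    for i in range(len(day) - 600 + 1):
        m = sum(day[i : i + 600]) / 600
        if m > best_m:
            best_m, best_mi = m, i
    best_l, best_li = math.inf, -1
    for i in range(len(day) - 300 + 1):
        m = sum(day[i : i + 300]) / 300
        if m < best_l:
            best_l, best_li = m, i
    return best_m, best_mi, best_l, best_li


def rankdata_simple(x) -> list[float]:
    """Midranks by direct comparison counting."""
    x = list(x)
    return [
        1 + sum(1 for v in x if v < xi) + (sum(1 for v in x if v == xi) - 1) / 2.0
        for xi in x
    ]


def mw_enum_p(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney (U of first sample, p) by enumerating
    every assignment of the pooled midranks to groups."""
    pooled = list(a) + list(b)
    ranks = rankdata_simple(pooled)
    n, na = len(pooled), len(a)
    mu = na * (n - na) / 2.0
    u_obs = sum(ranks[:na]) - na * (na + 1) / 2.0
    hits = total = 0
    for combo in itertools.combinations(range(n), na):
        u = sum(ranks[i] for i in combo) - na * (na + 1) / 2.0
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return u_obs, hits / total


def spearman_enum(x, y) -> tuple[float, float]:
    """Spearman rho of midranks and its exact two-sided permutation p."""
    rx, ry = rankdata_simple(x), rankdata_simple(y)
    n = len(rx)

    def pearson(u, v):
        mu, mv = sum(u) / n, sum(v) / n
        num = sum((a - mu) * (b - mv) for a, b in zip(u, v))
        den = math.sqrt(sum((a - mu) ** 2 for a in u) * sum((b - mv) ** 2 for b in v))
        return num / den

    rho = pearson(rx, ry)
    hits = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(pearson(rx, perm)) >= abs(rho) - 1e-12:
            hits += 1
    return rho, hits / total


def fisher_enum_p(table) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration
    (point-probability rule)."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def lchoose(m, k):
        return math.lgamma(m + 1) - math.lgamma(k + 1) - math.lgamma(m - k + 1)

    def prob(x):
        return math.exp(lchoose(r1, x) + lchoose(r2, c1 - x) - lchoose(n, c1))

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))
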