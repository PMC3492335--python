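"""Independent brute-force oracles used only by the test suite.

Each function recomputes a statistic from first principles (direct
enumeration or the textbook formula) without touching the package's
implementation paths.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def bh_stepup(pvalues):
    """Benjamini-Hochberg adjusted p-values by direct step-up enumeration."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running_min = min(running_min, p[idx] * m / rank)
        adj[idx] = running_min
    return np.minimum(adj, 1.0)


def bonferroni(pvalues):
    return np.minimum(np.asarray(pvalues, dtype=float) * len(pvalues), 1.0)


def pearson_chi2(a, b, c, d):
    """Pearson chi-square statistic from expected counts, 2x2, no correction."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    n = obs.sum()
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    exp = np.outer(row, col) / n
    return float(((obs - exp) ** 2 / exp).sum())


def odds_ratio_direct(a_vec, b_vec, haldane=True):
    """OR from two boolean vectors by direct gene enumeration."""
    a = b = c = d = 0
    for x, y in zip(a_vec, b_vec):
        if x and y:
            a += 1
        elif x:
            b += 1
        elif y:
            c += 1
        else:
            d += 1
    if haldane and 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def complete_linkage(dist):
    """O(n^3) agglomerative complete linkage on a square distance matrix.

    Returns the sorted list of merge heights (the tree shape is compared
    via heights; ties make leaf-level topology non-unique).
    """
    d = np.asarray(dist, dtype=float).copy()
    n = d.shape[0]
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                h = max(d[a, b] for a in clusters[i] for b in clusters[j])
                if h < best[0]:
                    best = (h, i, j)
        h, i, j = best
        heights.append(h)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return sorted(heights)


def exhaustive_permutation_p(values, weights, alternative="greater"):
    """Exact permutation p for the weighted-mean statistic, all n! shuffles.

    Uses the same add-one convention is NOT applied: this is the exact
    distribution, p = #{perm stat >= observed} / n! (>= includes the
    identity permutation, so p is never 0).
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    observed = float(v @ w)
    count = 0
    total = 0
    for perm in permutations(v):
        s = float(np.dot(perm, w))
        if alternative == "greater":
            count += s >= observed - 1e-12
        else:
            count += s <= observed + 1e-12
        total += 1
    return count / total
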