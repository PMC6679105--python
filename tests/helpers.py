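"""Independent oracles used by the unit and acceptance tests.

These deliberately avoid the code paths of the package itself: exact
integer enumeration for the Fisher and Mann-Whitney tests, an O(n^3)
textbook agglomeration for average linkage, and the plain defining formula
for Storey q-values.
"""

from itertools import combinations
from math import comb

import numpy as np

_TIE_NUM = 10**7  # relative pmf-tie tolerance 1e-7, as exact integers


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Works in exact integer arithmetic: the pmf of table k is
    C(n, k) C(M−n, N−k) / C(M, N); all tables whose (integer) numerator is
    ≤ the observed one, up to a 1e-7 relative tie tolerance, contribute.
    """
    M, n, N = a + b + c + d, a + b, a + c
    denom = comb(M, N)
    kmin, kmax = max(0, N - (M - n)), min(n, N)
    num_obs = comb(n, a) * comb(M - n, N - a)
    total = 0
    for k in range(kmin, kmax + 1):
        num_k = comb(n, k) * comb(M - n, N - k)
        if num_k * _TIE_NUM <= num_obs * (_TIE_NUM + 1):
            total += num_k
    return total / denom


def mannwhitney_two_sided_exact(x, y) -> float:
    """Two-sided rank-sum p by enumerating all C(m+n, m) group assignments.

    Assumes no ties between or within groups.  The two-sided p is the
    probability, under random assignment, of a U statistic at least as far
    from its mean mn/2 as the observed one.
    """
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    m, n = len(x), len(y)
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(rank[v] for v in x) - m * (m + 1) / 2
    dev_obs = abs(u_obs - m * n / 2)
    hits = total = 0
    for idx in combinations(range(m + n), m):
        u = sum(i + 1 for i in idx) - m * (m + 1) / 2
        if abs(u - m * n / 2) >= dev_obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def average_linkage_heights(dist: np.ndarray) -> list[float]:
    """Merge heights of textbook average-linkage agglomeration.

    ``dist`` is a full square distance matrix.  Clusters merge at the mean
    pairwise distance between their members; returns the sorted sequence
    of merge heights.
    """
    n = dist.shape[0]
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([dist[a, b] for a in clusters[i]
                             for b in clusters[j]])
                if d < best[0]:
                    best = (d, (i, j))
        h, (i, j) = best
        heights.append(h)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return heights


def storey_q_direct(p: np.ndarray, pi0: float) -> np.ndarray:
    """q_(i) = π0 · m · p_(i) / i with the reverse cumulative minimum."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = [pi0 * m * p[order[i]] / (i + 1) for i in range(m)]
    for i in range(m - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
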