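"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a statistic from first principles (exhaustive
enumeration, direct formula evaluation, or naive rescanning) without
touching the package's implementation path.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_average_linkage(d: np.ndarray) -> list[tuple[int, int, float, int]]:
    """O(n^3) agglomeration that rescans all original pairs each step.

    The inter-cluster distance is recomputed every step as the plain mean
    of all original pairwise distances between the two clusters' members.
    Ties break on the lexicographically smallest (id_a, id_b).  Returns
    merge rows (id_a, id_b, height, new_size) with leaves 0..n-1 and merge
    i creating cluster n+i.
    """
    n = d.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = []
    for step in range(n - 1):
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            dist = float(
                np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
            )
            key = (dist, a, b)
            if best is None or key < best:
                best = key
        dist, a, b = best
        members = clusters.pop(a) + clusters.pop(b)
        clusters[n + step] = members
        merges.append((a, b, dist, len(members)))
    return merges


def brute_force_partition(
    merges: list[tuple[int, int, float, int]], n: int, k: int
) -> list[frozenset[int]]:
    """Partition of the leaves after n - k merges of a merge list."""
    clusters: dict[int, set[int]] = {i: {i} for i in range(n)}
    for step in range(n - k):
        a, b, _, _ = merges[step]
        clusters[n + step] = clusters.pop(a) | clusters.pop(b)
    return sorted((frozenset(c) for c in clusters.values()), key=min)


def calinski_harabasz_formula(x: np.ndarray, labels: np.ndarray) -> float:
    """Direct evaluation of (B/(k-1)) / (W/(n-k)) with explicit loops."""
    x = np.asarray(x, dtype=float)
    uniq = sorted(set(labels.tolist()))
    n, k = len(x), len(uniq)
    grand = sum(x) / n
    b = 0.0
    w = 0.0
    for lab in uniq:
        pts = x[np.asarray(labels) == lab]
        mean = sum(pts) / len(pts)
        b += len(pts) * float(((mean - grand) ** 2).sum())
        for p in pts:
            w += float(((p - mean) ** 2).sum())
    if w == 0:
        return float("inf")
    return (b / (k - 1)) / (w / (n - k))


def wilcoxon_exact_enumeration(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments.

    Tie-free samples only.  Uses the Mann-Whitney U of the first group and
    counts assignments at least as extreme (|U - n1 n2 / 2|).
    """
    pooled = np.concatenate([x, y])
    assert len(np.unique(pooled)) == len(pooled), "oracle requires tie-free data"
    n1 = len(x)
    order = np.argsort(pooled)
    ranks = np.empty(len(pooled))
    ranks[order] = np.arange(1, len(pooled) + 1)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    center = n1 * len(y) / 2
    extreme = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        extreme += abs(u - center) >= abs(u_obs - center) - 1e-12
        total += 1
    return extreme / total


def kruskal_wallis_formula(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H from the textbook formula."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n)
    # average ranks for ties
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)].sum()
        h += r**2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n)
    return h / correction


def mcnemar_exact_formula(b: int, c: int) -> float:
    """Two-sided exact McNemar p: binomial(b+c, 1/2) tail mass."""
    n = b + c
    if n == 0:
        return 1.0
    pmf = [math.comb(n, k) * 0.5**n for k in range(n + 1)]
    p_obs = pmf[b]
    return min(1.0, sum(p for p in pmf if p <= p_obs + 1e-12))
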