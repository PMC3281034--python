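"""Hierarchical clustering of contact location profiles into mixing types.

Subject-day profiles (6-vectors of normalized PCH shares) are clustered by
agglomerative hierarchical clustering with unweighted average linkage
(UPGMA-style on an arbitrary distance table; weighted-average, centroid and
complete linkage are also available since profile clusterings tend to be
robust to the linkage choice).  Distances are Euclidean in share space.

The number of clusters is chosen by the Caliński–Harabasz pseudo-F
statistic evaluated on the hierarchical cuts — no re-partitioning step —
optionally capped for interpretability (clusterings of six setting shares
are conventionally capped at six clusters, one per possible dominant
setting).  Each cluster is labelled by the setting with the largest mean
share: HD/OD/RD/SD/TD/WD for home/other/retail/social/travel/work-dominated
mixing types.

The implementation is deliberately deterministic: merge ties are broken by
the lexicographically smallest pair of cluster indices (original leaves are
0..n-1; the cluster created by merge i is n+i), so identical inputs always
yield identical trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diary_model import DOMINANT_LABELS, SETTINGS

__all__ = [
    "Dendrogram",
    "ClusterResult",
    "profile_distance",
    "distance_matrix",
    "average_linkage",
    "cut",
    "calinski_harabasz",
    "select_k",
    "label_clusters",
    "occupancy_table",
    "membership_diversity",
]

LINKAGES = ("average", "weighted", "centroid", "complete")


def profile_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Euclidean distance between two profiles in share space."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("profiles must have equal length")
    return float(np.sqrt(np.sum((p - q) ** 2)))


def distance_matrix(x: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distance matrix of profile rows."""
    x = np.asarray(x, dtype=float)
    sq = np.sum(x**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.maximum(d2, 0.0, out=d2)
    d = np.sqrt(d2)
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class Dendrogram:
    """Merge history of an agglomerative clustering.

    ``merges`` holds one row per merge: (id_a, id_b, linkage_distance,
    new_size) with id_a < id_b; original leaves are 0..n-1 and merge i
    creates cluster id n+i (the scipy linkage convention).
    """

    merges: np.ndarray  # (n-1, 4) float array
    n_leaves: int

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=float)
        if self.merges.shape != (max(self.n_leaves - 1, 0), 4):
            raise ValueError("merge list must have n_leaves - 1 rows of 4")

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def average_linkage(
    distances: np.ndarray, method: str = "average"
) -> Dendrogram:
    """Agglomerative clustering of a symmetric distance table.

    At each step the pair of clusters with the smallest inter-cluster
    distance is merged; for ``average`` linkage that distance is the
    unweighted mean of all original between-cluster pairwise distances
    (maintained by the Lance–Williams recurrence).  Ties are broken by the
    lexicographically lowest (id_a, id_b).

    Parameters
    ----------
    distances
        Square symmetric matrix with zero diagonal.
    method
        "average" (UPGMA), "weighted" (WPGMA), "centroid" or "complete".
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    if method not in LINKAGES:
        raise ValueError(f"unknown linkage {method!r}; expected one of {LINKAGES}")

    n = d.shape[0]
    if n == 0:
        return Dendrogram(merges=np.empty((0, 4)), n_leaves=0)

    # centroid linkage uses the Lance-Williams recurrence on squared
    # distances; the reported height is the (signed-safe) square root.
    squared = method == "centroid"
    work = d**2 if squared else d.copy()
    np.fill_diagonal(work, np.inf)

    ids = list(range(n))  # active cluster ids, position-aligned with `work`
    sizes = [1] * n
    active = np.ones(n, dtype=bool)
    merges = np.empty((n - 1, 4))

    for step in range(n - 1):
        sub = work[np.ix_(active, active)]
        pos = np.flatnonzero(active)
        best = np.min(sub)
        cand = np.argwhere(np.isclose(sub, best, rtol=0.0, atol=0.0))
        # candidate (i, j) in submatrix coordinates, i < j; choose the
        # lexicographically smallest (id_a, id_b)
        pairs = []
        for i, j in cand:
            if i < j:
                a, b = ids[pos[i]], ids[pos[j]]
                pairs.append((min(a, b), max(a, b), pos[i], pos[j]))
        id_a, id_b, pi, pj = min(pairs)
        height = np.sqrt(best) if squared else best
        size_new = sizes[pi] + sizes[pj]
        merges[step] = (id_a, id_b, height, size_new)

        # Lance-Williams update into slot pi; retire slot pj.
        ni, nj = sizes[pi], sizes[pj]
        others = active.copy()
        others[pi] = others[pj] = False
        dk_i = work[others, pi]
        dk_j = work[others, pj]
        if method == "average":
            new = (ni * dk_i + nj * dk_j) / (ni + nj)
        elif method == "weighted":
            new = 0.5 * (dk_i + dk_j)
        elif method == "complete":
            new = np.maximum(dk_i, dk_j)
        else:  # centroid, on squared distances
            new = (
                ni * dk_i + nj * dk_j
            ) / (ni + nj) - ni * nj * work[pi, pj] / (ni + nj) ** 2
        work[others, pi] = new
        work[pi, others] = new
        active[pj] = False
        ids[pi] = n + step
        sizes[pi] = size_new

    return Dendrogram(merges=merges, n_leaves=n)


def cut(dendrogram: Dendrogram, k: int) -> np.ndarray:
    """Cluster assignments after n - k merges.

    Returns integer labels 0..k-1 per leaf, numbered by each cluster's
    smallest leaf index (deterministic).
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    roots: dict[int, int] = {i: i for i in range(n)}  # cluster id -> root
    for step in range(n - k):
        a, b = int(dendrogram.merges[step, 0]), int(dendrogram.merges[step, 1])
        ra, rb = find(roots[a]), find(roots[b])
        parent[rb] = ra
        members[ra].extend(members.pop(rb))
        roots[n + step] = ra

    clusters = sorted(members.values(), key=min)
    labels = np.empty(n, dtype=int)
    for lab, leaves in enumerate(clusters):
        labels[leaves] = lab
    return labels


def calinski_harabasz(x: np.ndarray, assignments: np.ndarray) -> float:
    """Caliński–Harabasz pseudo-F: (B/(k-1)) / (W/(n-k)), Euclidean.

    B is the size-weighted squared distance of cluster means from the
    grand mean, W the within-cluster sum of squared distances from cluster
    means.  Perfectly tight clusters (W = 0) return +inf.
    """
    x = np.asarray(x, dtype=float)
    assignments = np.asarray(assignments)
    n = x.shape[0]
    labels = np.unique(assignments)
    k = len(labels)
    if k < 2:
        raise ValueError("pseudo-F requires k >= 2")
    if n == k:
        return float("inf")  # all-singleton partition: W = 0 sentinel
    if n < k:
        raise ValueError("pseudo-F requires n >= k")
    grand = x.mean(axis=0)
    b = 0.0
    w = 0.0
    for lab in labels:
        pts = x[assignments == lab]
        mean = pts.mean(axis=0)
        b += len(pts) * float(np.sum((mean - grand) ** 2))
        w += float(np.sum((pts - mean) ** 2))
    if w == 0.0:
        return float("inf")
    return (b / (k - 1)) / (w / (n - k))


@dataclass
class ClusterResult:
    """Chosen partition of profiles into setting-dominated mixing types."""

    dendrogram: Dendrogram
    assignments: np.ndarray  # labels 0..k-1 per profile
    pseudo_f: dict[int, float]  # k -> pseudo-F on the hierarchical cut
    chosen_k: int
    argmax_k: int
    labels: list[str]  # per-cluster dominant-setting code (HD, WD, ...)
    mean_profiles: pd.DataFrame  # cluster x setting mean shares
    duplicate_labels: bool = field(default=False)


def select_k(
    x: np.ndarray,
    dendrogram: Dendrogram,
    k_max: int = 10,
    cap: int | None = 6,
) -> ClusterResult:
    """Choose the cluster count by pseudo-F over hierarchical cuts.

    Evaluates the pseudo-F at every cut k in [2, k_max]; the chosen k is
    the argmax (smallest k on ties), reduced to ``cap`` when the argmax
    exceeds it — the interpretability cap mirrors limiting six setting
    shares to at most six setting-dominated types.  Pass ``cap=None`` for
    uncapped selection (used by archetype-recovery checks).
    """
    n = dendrogram.n_leaves
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    k_hi = min(k_max, n - 1)
    pseudo_f: dict[int, float] = {}
    for k in range(2, k_hi + 1):
        pseudo_f[k] = calinski_harabasz(x, cut(dendrogram, k))
    if not pseudo_f:
        raise ValueError("no admissible k in [2, k_max]")
    argmax_k = min(
        (k for k, v in pseudo_f.items() if v == max(pseudo_f.values()))
    )
    chosen = argmax_k if cap is None else min(argmax_k, cap)
    assignments = cut(dendrogram, chosen)
    if np.asarray(x).shape[1] == len(SETTINGS):
        labels, means, duplicated = label_clusters(x, assignments)
    else:  # generic feature space: cluster means without setting labels
        cluster_ids = np.unique(assignments)
        means = pd.DataFrame(
            [np.asarray(x)[assignments == c].mean(axis=0) for c in cluster_ids],
            index=cluster_ids,
        )
        labels, duplicated = [], False
    return ClusterResult(
        dendrogram=dendrogram,
        assignments=assignments,
        pseudo_f=pseudo_f,
        chosen_k=chosen,
        argmax_k=argmax_k,
        labels=labels,
        mean_profiles=means,
        duplicate_labels=duplicated,
    )


def label_clusters(
    x: np.ndarray, assignments: np.ndarray
) -> tuple[list[str], pd.DataFrame, bool]:
    """Label each cluster by the setting with the largest mean share.

    Ties break by canonical setting order.  Duplicate labels (two clusters
    dominated by the same setting) are permitted and flagged.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[1] != len(SETTINGS):
        raise ValueError(f"profiles must have {len(SETTINGS)} columns")
    assignments = np.asarray(assignments)
    cluster_ids = np.unique(assignments)
    rows = []
    labels = []
    for cid in cluster_ids:
        mean = x[assignments == cid].mean(axis=0)
        rows.append(mean)
        dominant = SETTINGS[int(np.argmax(mean))]  # argmax takes first on ties
        labels.append(DOMINANT_LABELS[dominant])
    means = pd.DataFrame(rows, index=cluster_ids, columns=list(SETTINGS))
    means.index.name = "cluster"
    duplicated = len(set(labels)) < len(labels)
    return labels, means, duplicated


def occupancy_table(
    labels_per_point: Sequence[str], days: Sequence[str]
) -> pd.DataFrame:
    """Subject-day counts per (day, mixing-type label), with totals.

    Rows are days (plus "Total"), columns the label codes present; row
    sums equal the number of clustered subject-days per day.
    """
    df = pd.DataFrame({"day": list(days), "label": list(labels_per_point)})
    if len(df) == 0:
        raise ValueError("occupancy table requires at least one subject-day")
    table = pd.crosstab(df["day"], df["label"])
    order = [c for c in DOMINANT_LABELS.values() if c in table.columns]
    table = table.reindex(columns=order)
    day_order = [d for d in ("Wed", "Fri", "Sun") if d in table.index]
    extra = [d for d in table.index if d not in day_order]
    table = table.reindex(day_order + extra)
    table.loc["Total"] = table.sum(axis=0)
    return table


def membership_diversity(
    assignments_by_day: pd.DataFrame,
) -> tuple[pd.Series, Mapping[str, float]]:
    """Distinct mixing-type labels per subject across survey days.

    ``assignments_by_day`` needs columns subject_id and label (one row per
    subject-day).  Returns the per-subject count plus mean/median/IQR.
    """
    required = {"subject_id", "label"}
    if not required.issubset(assignments_by_day.columns):
        raise ValueError(f"need columns {sorted(required)}")
    counts = assignments_by_day.groupby("subject_id")["label"].nunique()
    counts.name = "n_unique_labels"
    summary = {
        "mean": float(counts.mean()),
        "median": float(counts.median()),
        "q1": float(counts.quantile(0.25)),
        "q3": float(counts.quantile(0.75)),
    }
    return counts, summary
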