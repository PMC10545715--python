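"""Dimensional reduction of the temporal transcriptome: log-relative
profiles, UPGMA agglomeration, Davies-Bouldin-guided cluster-count
selection and per-cluster activity averaging.

Each gene's expression is made shape-comparable by dividing by its own
across-timepoint mean before the log transform; UPGMA (size-weighted
average linkage) then groups genes with similar temporal shapes, the
dendrogram is cut at the K minimising the Davies-Bouldin index, and
cluster activity is the intra-cluster mean profile laid out on a fixed
near-square grid so snapshots from different time points are positionally
comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform


@dataclass
class ProfileMatrix:
    values: pd.DataFrame       # genes x timepoints, log-relative
    log_base: float
    pseudocount: float
    reference: str = "per-gene across-timepoint mean"
    dropped_genes: list[str] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return len(self.values)


@dataclass
class Dendrogram:
    merges: np.ndarray   # (n-1, 4): node_a, node_b, height, new_size
    leaf_ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)


@dataclass
class ClusterSelection:
    candidate_k: list[int]
    scores: dict[int, float]
    chosen_k: int
    assignments: np.ndarray  # cluster label per gene (0..K-1)


@dataclass
class ClusterActivityMap:
    activity: pd.DataFrame   # clusters x timepoints
    sizes: pd.Series
    grid: pd.DataFrame       # cluster -> (row, col) on the fixed layout


def log_relative_transform(
    matrix: pd.DataFrame, pseudocount: float = 1.0, log_base: float = 2.0
) -> ProfileMatrix:
    """Divide each gene by its across-timepoint mean and take logs.

    Rows that are all zero carry no shape information and are removed
    (reported in dropped_genes); rows containing a zero receive the
    pseudocount before the ratio so the log stays finite. Zero-free rows
    are left untouched, making the transform scale-invariant for them.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two timepoints")
    vals = matrix.astype(float)
    all_zero = (vals == 0).all(axis=1)
    dropped = list(vals.index[all_zero])
    vals = vals.loc[~all_zero]
    if vals.empty:
        raise ValueError("all genes are all-zero")
    has_zero = (vals == 0).any(axis=1)
    vals = vals.where(~has_zero, vals + pseudocount, axis=0)
    rel = vals.div(vals.mean(axis=1), axis=0)
    out = np.log(rel) / math.log(log_base)
    return ProfileMatrix(out, log_base, pseudocount, dropped_genes=dropped)


def _distance_matrix(X: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        D = squareform(pdist(X, metric="euclidean"))
    elif metric == "correlation":
        D = squareform(pdist(X, metric="correlation"))
    else:
        raise ValueError(f"unsupported metric {metric!r}")
    if not np.isfinite(D).all():
        raise ValueError("non-finite distances")
    return D


def upgma(profiles: ProfileMatrix | pd.DataFrame, metric: str = "euclidean") -> Dendrogram:
    """Size-weighted average-linkage agglomeration with a deterministic
    tie-break: among equally close pairs, merge the one whose sorted
    (smallest-leaf, smallest-leaf) representative pair is lexicographically
    least. Merge heights must be non-decreasing (guaranteed for UPGMA on a
    metric; violation raises)."""
    df = profiles.values if isinstance(profiles, ProfileMatrix) else profiles
    X = df.to_numpy(dtype=float)
    n = len(X)
    if n < 2:
        raise ValueError("need at least two genes")
    D = _distance_matrix(X, metric)

    INF = np.inf
    work = D.copy()
    np.fill_diagonal(work, INF)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n, dtype=float)
    reps = np.arange(n)           # smallest original leaf in each cluster
    node_ids = np.arange(n)       # scipy-style node numbering
    merges = np.zeros((n - 1, 4))
    last_height = -INF
    for step in range(n - 1):
        dmin = work[np.ix_(active, active)].min()
        ii, jj = np.nonzero((work == dmin) & active[:, None] & active[None, :])
        pairs = [
            (min(reps[a], reps[b]), max(reps[a], reps[b]), a, b)
            for a, b in zip(ii, jj)
            if a < b
        ]
        _, _, a, b = min(pairs)
        if dmin < last_height - 1e-12:
            raise ValueError("non-monotone merge heights")
        last_height = max(last_height, dmin)
        na, nb = sizes[a], sizes[b]
        merged = (work[a] * na + work[b] * nb) / (na + nb)
        work[a] = merged
        work[:, a] = merged
        work[a, a] = INF
        active[b] = False
        work[b, :] = INF
        work[:, b] = INF
        merges[step] = (
            min(node_ids[a], node_ids[b]),
            max(node_ids[a], node_ids[b]),
            dmin,
            na + nb,
        )
        sizes[a] = na + nb
        reps[a] = min(reps[a], reps[b])
        node_ids[a] = n + step
    return Dendrogram(merges, list(df.index))


def cut_dendrogram(dend: Dendrogram, k: int) -> np.ndarray:
    """Labels (0..k-1) from applying the first n-k merges; label numbering
    follows the smallest leaf index in each cluster."""
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        a, b = int(dend.merges[step, 0]), int(dend.merges[step, 1])
        node = n + step
        parent[find(a)] = node
        parent[find(b)] = node
    roots: dict[int, int] = {}
    raw = np.array([find(i) for i in range(n)])
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in roots:
            roots[r] = len(roots)
        labels[i] = roots[r]
    return labels


def davies_bouldin(
    assignments: np.ndarray, profiles: ProfileMatrix | pd.DataFrame
) -> float:
    """DB = (1/K) * sum_i max_{j != i} (S_i + S_j) / M_ij with S_i the mean
    member-to-centroid distance and M_ij the centroid separation.
    Singletons have S = 0; coincident centroids make the pair ratio +inf
    (flagged through the returned value)."""
    df = profiles.values if isinstance(profiles, ProfileMatrix) else profiles
    X = df.to_numpy(dtype=float)
    labels = np.asarray(assignments)
    uniq = np.unique(labels)
    K = len(uniq)
    if K < 2:
        raise ValueError("need at least two non-empty clusters")
    centroids = np.vstack([X[labels == c].mean(axis=0) for c in uniq])
    scatter = np.array(
        [
            np.linalg.norm(X[labels == c] - centroids[i], axis=1).mean()
            for i, c in enumerate(uniq)
        ]
    )
    M = cdist(centroids, centroids)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (scatter[:, None] + scatter[None, :]) / M
    np.fill_diagonal(R, -np.inf)
    worst = R.max(axis=1)
    return float(worst.mean())


def select_cluster_count(
    dend: Dendrogram,
    profiles: ProfileMatrix | pd.DataFrame,
    k_min: int = 2,
    k_max: int | None = None,
) -> ClusterSelection:
    """Cut at every K in [k_min, k_max], score each cut with the
    Davies-Bouldin index and keep the minimiser (ties -> smallest K)."""
    n = dend.n_leaves
    if k_max is None:
        k_max = min(max(k_min, int(np.ceil(n / 2))), 400)
    if k_min < 2 or k_max > n - 1 or k_min > k_max:
        raise ValueError(f"invalid K range [{k_min}, {k_max}] for n={n}")
    scores: dict[int, float] = {}
    best_k, best_score = None, np.inf
    for k in range(k_min, k_max + 1):
        labels = cut_dendrogram(dend, k)
        s = davies_bouldin(labels, profiles)
        scores[k] = s
        if s < best_score:
            best_k, best_score = k, s
    return ClusterSelection(
        candidate_k=list(range(k_min, k_max + 1)),
        scores=scores,
        chosen_k=best_k,
        assignments=cut_dendrogram(dend, best_k),
    )


def cluster_activity(
    profiles: ProfileMatrix | pd.DataFrame, assignments: np.ndarray
) -> ClusterActivityMap:
    """Per-cluster arithmetic mean profile plus a fixed row-major
    near-square grid layout in cluster-id order."""
    df = profiles.values if isinstance(profiles, ProfileMatrix) else profiles
    labels = np.asarray(assignments)
    if len(labels) != len(df):
        raise ValueError("one assignment per gene required")
    uniq = np.unique(labels)
    rows, sizes = {}, {}
    for c in uniq:
        members = df[labels == c]
        if members.empty:
            raise ValueError(f"empty cluster {c}")
        rows[c] = members.mean(axis=0)
        sizes[c] = len(members)
    activity = pd.DataFrame(rows).T
    activity.index.name = "cluster"
    ncol = int(np.ceil(np.sqrt(len(uniq))))
    grid = pd.DataFrame(
        {
            "row": [i // ncol for i in range(len(uniq))],
            "col": [i % ncol for i in range(len(uniq))],
        },
        index=uniq,
    )
    return ClusterActivityMap(
        activity=activity, sizes=pd.Series(sizes), grid=grid
    )
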