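"""Single-dataset clustering of Hi-C bins: the 15 method variants.

Three algorithm families (hierarchical with rebalancing, k-means, spectral)
crossed with five distance/similarity choices (Euclidean, Pearson,
Spearman, contact count, log2 contact count).  All methods operate on a
normalized contact matrix; distance-based methods work on log2(x+1) rows,
the count-based ones directly on the (log) counts.

Custom variants implemented here because no stock routine provides them:

* ``kmeans_spearman`` — Lloyd-style k-means with 1 - Spearman correlation
  as the assignment distance and arithmetic-mean centroids;
* ``kmeans_counts`` — graph k-means on the contact map itself: each bin is
  reassigned to the cluster maximising its mean (log) contact count to the
  cluster's current members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.cluster import KMeans

from .bins_io import ContactMatrix
from .graph import SpectralEmbedding

logger = logging.getLogger(__name__)

DISTANCE_METRICS = ("euclidean", "one_minus_pearson", "one_minus_spearman",
                    "count", "logcount")
MAX_ITER = 300


@dataclass
class ClusterAssignment:
    """Per-bin labels in {0..k-1} for one dataset."""

    labels: np.ndarray
    k: int
    method: str = ""
    seed: int | None = None

    def __post_init__(self):
        lab = np.asarray(self.labels, dtype=int)
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if len(lab) and (lab.min() < 0 or lab.max() >= self.k):
            raise ValueError("labels out of range for k")
        self.labels = lab

    @property
    def n(self) -> int:
        return len(self.labels)

    def members(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.labels == c)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


@dataclass
class DistanceMatrix:
    values: np.ndarray
    metric: str

    def __post_init__(self):
        d = np.asarray(self.values, dtype=float)
        if not np.allclose(d, d.T, atol=1e-9, rtol=0):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(d) != 0).any():
            raise ValueError("distance matrix must have zero diagonal")
        if (d < 0).any():
            raise ValueError("distances must be nonnegative")
        self.values = d

    @property
    def n(self) -> int:
        return self.values.shape[0]


def distance_matrix(m: ContactMatrix, metric: str) -> DistanceMatrix:
    """Pairwise bin distances under one of the five conventions.

    Count metrics turn similarity into distance by subtracting from the
    matrix maximum (the most-interacting pair is at distance 0); the rest
    are computed between log2 rows.
    """
    if metric not in DISTANCE_METRICS:
        raise ValueError(f"metric must be one of {DISTANCE_METRICS}")
    if metric in ("count", "logcount"):
        base = m.counts if metric == "count" else m.log2p1()
        d = base.max() - base
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix(d, metric)
    rows = m.log2p1()
    if metric == "euclidean":
        d = squareform(pdist(rows, metric="euclidean"))
    else:
        data = rows
        if metric == "one_minus_spearman":
            data = np.apply_along_axis(rankdata, 1, rows)
        sd = data.std(axis=1)
        constant = sd == 0
        safe = data.copy()
        safe[constant] = np.arange(rows.shape[1])
        c = np.corrcoef(safe)
        # constant rows have undefined correlation -> treat as uncorrelated
        c[constant, :] = 0.0
        c[:, constant] = 0.0
        np.fill_diagonal(c, 1.0)
        d = 1.0 - c
        d = np.clip((d + d.T) / 2.0, 0.0, None)
        np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, metric)


def _average_linkage_cut(d: np.ndarray, idx: np.ndarray, k: int) -> np.ndarray:
    """Cut an average-linkage tree of the submatrix d[idx][:,idx] into at
    most k clusters; returns labels for idx positions."""
    if len(idx) <= k:
        return np.arange(len(idx))
    sub = d[np.ix_(idx, idx)]
    z = linkage(squareform(sub, checks=False), method="average")
    return fcluster(z, t=k, criterion="maxclust") - 1


def hierarchical_cluster(d: DistanceMatrix, k: int,
                         min_size: int = 10) -> ClusterAssignment:
    """Average-linkage clustering with size rebalancing.

    After the maxclust cut, the largest cluster is repeatedly split in two
    (re-running average linkage within it) until k clusters of at least
    ``min_size`` members exist, then clusters smaller than ``min_size`` are
    absorbed into the largest cluster.
    """
    n = d.n
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError("fewer points than clusters")
    labels = _average_linkage_cut(d.values, np.arange(n), k)
    if min_size > 1:
        next_label = labels.max() + 1
        for _ in range(n):  # each split shrinks the largest cluster
            sizes = np.bincount(labels)
            if (sizes >= min_size).sum() >= k:
                break
            largest = int(np.argmax(sizes))
            members = np.flatnonzero(labels == largest)
            if len(members) < 2:
                break
            sub = _average_linkage_cut(d.values, members, 2)
            if sub.max() == 0:  # linkage refused to split (all identical)
                break
            labels[members[sub == 1]] = next_label
            next_label += 1
        sizes = np.bincount(labels)
        small = np.flatnonzero((sizes > 0) & (sizes < min_size))
        if len(small):
            largest = int(np.argmax(sizes))
            for c in small:
                if c != largest:
                    labels[labels == c] = largest
    # compact labels to 0..k'-1
    uniq, labels = np.unique(labels, return_inverse=True)
    return ClusterAssignment(labels, k=len(uniq),
                             method=f"hier_{d.metric}")


def _run_kmeans(points: np.ndarray, k: int, seed: int,
                restarts: int) -> np.ndarray:
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed,
                max_iter=MAX_ITER)
    return km.fit_predict(points)


def kmeans_vector(m: ContactMatrix, metric: str, k: int, seed: int = 0,
                  restarts: int = 10) -> ClusterAssignment:
    """Standard k-means on log2 rows; the Pearson variant z-scores each row
    first, which makes Euclidean distance monotone in 1 - correlation."""
    if metric not in ("euclidean", "pearson"):
        raise ValueError("metric must be 'euclidean' or 'pearson'")
    rows = m.log2p1()
    if metric == "pearson":
        mu = rows.mean(axis=1, keepdims=True)
        sd = rows.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        rows = (rows - mu) / sd
    labels = _run_kmeans(rows, k, seed, restarts)
    return ClusterAssignment(labels, k=k, method=f"kmeans_{metric}",
                             seed=seed)


def _spearman_distance_to_centroids(ranked_rows: np.ndarray,
                                    centroids: np.ndarray) -> np.ndarray:
    """1 - Spearman correlation of each row against each centroid.

    Rows are pre-ranked; centroids are ranked here.  A constant centroid
    has undefined correlation and gets the worst distance, 1.
    """
    rc = np.apply_along_axis(rankdata, 1, centroids)
    r = ranked_rows - ranked_rows.mean(axis=1, keepdims=True)
    c = rc - rc.mean(axis=1, keepdims=True)
    rn = np.linalg.norm(r, axis=1)
    cn = np.linalg.norm(c, axis=1)
    corr = (r @ c.T) / np.outer(np.where(rn == 0, 1, rn),
                                np.where(cn == 0, 1, cn))
    corr[:, cn == 0] = 0.0
    corr[rn == 0, :] = 0.0
    if (cn == 0).any():
        logger.warning("constant centroid: Spearman distance set to 1")
    return 1.0 - corr


def kmeans_spearman(m: ContactMatrix, k: int, seed: int = 0,
                    restarts: int = 10) -> ClusterAssignment:
    """k-means with 1 - Spearman rank correlation as the distance.

    Centroids are arithmetic means of member rows; a point is assigned to
    the centroid with the highest rank correlation to it.  The objective
    (sum of assigned distances) is checked each sweep and iteration stops
    as soon as it fails to decrease, so the reported trace is monotone.
    """
    rows = m.log2p1()
    n = rows.shape[0]
    ranked = np.apply_along_axis(rankdata, 1, rows)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        centers = rows[rng.choice(n, size=k, replace=False)].copy()
        labels = np.zeros(n, dtype=int)
        prev_obj = np.inf
        for _ in range(MAX_ITER):
            dist = _spearman_distance_to_centroids(ranked, centers)
            new_labels = dist.argmin(axis=1)
            obj = dist[np.arange(n), new_labels].sum()
            if obj >= prev_obj - 1e-12:
                break
            labels, prev_obj = new_labels, obj
            for c in range(k):
                sel = new_labels == c
                if sel.any():
                    centers[c] = rows[sel].mean(axis=0)
                else:
                    far = dist.min(axis=1).argmax()
                    centers[c] = rows[far]
        if best is None or prev_obj < best[0]:
            best = (prev_obj, labels)
    return ClusterAssignment(best[1], k=k, method="kmeans_spearman",
                             seed=seed)


def kmeans_counts(m: ContactMatrix, k: int, log: bool = False, seed: int = 0,
                  restarts: int = 10) -> ClusterAssignment:
    """Graph k-means on the contact map.

    Affinity of bin i to cluster c is the mean (log) contact count between
    i and the current members of c (excluding the self pair).  Each sweep
    reassigns every bin to its maximum-affinity cluster; a sweep that does
    not improve the total within-cluster affinity is rolled back, making
    the objective non-decreasing.
    """
    w = m.log2p1() if log else m.counts
    n = w.shape[0]
    rng = np.random.default_rng(seed)

    def affinities(labels):
        onehot = np.zeros((n, k))
        onehot[np.arange(n), labels] = 1.0
        sums = w @ onehot                      # contact mass to each cluster
        sizes = onehot.sum(axis=0)
        denom = sizes[None, :] - onehot        # members excluding self
        with np.errstate(divide="ignore", invalid="ignore"):
            aff = np.where(denom > 0, sums / np.maximum(denom, 1), 0.0)
        return aff

    def objective(labels):
        return affinities(labels)[np.arange(n), labels].sum()

    best = None
    for _ in range(restarts):
        labels = rng.integers(0, k, size=n)
        prev_obj = objective(labels)
        for _ in range(MAX_ITER):
            aff = affinities(labels)
            new_labels = aff.argmax(axis=1)
            # repair empty clusters with the globally least-connected bins
            for c in range(k):
                if not (new_labels == c).any():
                    low = aff.max(axis=1).argmin()
                    new_labels[low] = c
            obj = objective(new_labels)
            if obj <= prev_obj + 1e-12:
                break  # non-improving sweep rolled back
            labels, prev_obj = new_labels, obj
        if best is None or prev_obj > best[0]:
            best = (prev_obj, labels)
    method = "kmeans_logcount" if log else "kmeans_count"
    return ClusterAssignment(best[1], k=k, method=method, seed=seed)


def spectral_cluster(e: SpectralEmbedding, k: int, seed: int = 0,
                     restarts: int = 10) -> ClusterAssignment:
    """k-means on the rows of the top-k eigenvector matrix."""
    if e.k < k:
        raise ValueError("embedding has fewer columns than k")
    labels = _run_kmeans(e.X[:, :k], k, seed, restarts)
    return ClusterAssignment(labels, k=k, method=f"spectral_{e.metric}",
                             seed=seed)
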