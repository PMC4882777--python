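"""Weighted-graph construction and spectral embedding of contact maps.

A normalized Hi-C map is turned into a weighted similarity graph under one
of five metrics, then embedded via the top eigenvectors of the symmetric
normalized Laplacian L = D^{-1/2} A D^{-1/2}:

* ``euclidean``  — A(i,j) = M - e_ij where e_ij is the Euclidean distance
  between rows i and j of the log2 matrix and M the maximum observed
  pairwise distance (so the most dissimilar pair gets weight 0);
* ``pearson`` / ``spearman`` — A(i,j) = c_ij clipped at 0 (negative
  correlations carry no edge);
* ``count`` / ``logcount`` — the (log2 of the) normalized counts
  themselves are the edge weights.

Correlations and distances are computed on log2(x+1)-transformed rows,
including the diagonal entry of each row; self-loops A(i,i) are zeroed for
the correlation metrics so they never dominate degrees.

``suggest_max_k`` implements the randomized-graph heuristic for bounding
the number of clusters: the weight multiset of the upper triangle is
shuffled to build null graphs and the observed Laplacian spectrum is
compared against the null spectrum position by position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .bins_io import ContactMatrix

logger = logging.getLogger(__name__)

METRICS = ("euclidean", "pearson", "spearman", "count", "logcount")
CORRELATION_METRICS = ("pearson", "spearman")


@dataclass
class SimilarityGraph:
    adjacency: np.ndarray
    metric: str

    def __post_init__(self):
        a = np.asarray(self.adjacency, dtype=float)
        if not np.allclose(a, a.T, atol=1e-9, rtol=0):
            raise ValueError("adjacency must be symmetric")
        if not np.isfinite(a).all():
            raise ValueError("adjacency must be finite")
        if (a < -1e-12).any():
            raise ValueError("adjacency must be nonnegative")
        self.adjacency = np.clip(a, 0.0, None)

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class LaplacianMatrix:
    """Symmetric normalized Laplacian; vertices with zero degree were
    removed, with ``kept`` mapping Laplacian rows back to graph vertices."""

    L: np.ndarray
    degrees: np.ndarray
    kept: np.ndarray

    @property
    def n(self) -> int:
        return self.L.shape[0]


@dataclass
class SpectralEmbedding:
    """Top-k eigenvectors (columns of X) of the normalized Laplacian,
    eigenvalues in descending order."""

    X: np.ndarray
    eigenvalues: np.ndarray
    metric: str = ""
    kept: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]


def _correlation_adjacency(rows: np.ndarray, rank: bool) -> np.ndarray:
    data = rows
    if rank:
        data = np.apply_along_axis(rankdata, 1, rows)
    sd = data.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant rows: correlation undefined, similarity "
                       "set to 0", int(constant.sum()))
    safe = data.copy()
    safe[constant] = np.arange(rows.shape[1])  # placeholder, zeroed below
    c = np.corrcoef(safe)
    c[constant, :] = 0.0
    c[:, constant] = 0.0
    a = np.clip(c, 0.0, None)
    np.fill_diagonal(a, 0.0)
    return a


def build_adjacency(m: ContactMatrix, metric: str) -> SimilarityGraph:
    """Build the weighted similarity graph for one of the five metrics."""
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if metric == "count":
        a = m.counts.copy()
    elif metric == "logcount":
        a = m.log2p1()
    else:
        rows = m.log2p1()
        if metric == "euclidean":
            from scipy.spatial.distance import squareform, pdist
            e = squareform(pdist(rows, metric="euclidean"))
            a = e.max() - e
        else:
            a = _correlation_adjacency(rows, rank=(metric == "spearman"))
    return SimilarityGraph(a, metric)


def laplacian(g: SimilarityGraph) -> LaplacianMatrix:
    """L = D^{-1/2} A D^{-1/2}; zero-degree vertices are dropped."""
    a = g.adjacency
    deg = a.sum(axis=1)
    kept = np.flatnonzero(deg > 0)
    if len(kept) < g.n:
        logger.warning("removed %d isolated vertices before Laplacian",
                       g.n - len(kept))
    if len(kept) == 0:
        raise ValueError("graph has no edges")
    a = a[np.ix_(kept, kept)]
    deg = deg[kept]
    inv_sqrt = 1.0 / np.sqrt(deg)
    L = a * np.outer(inv_sqrt, inv_sqrt)
    L = (L + L.T) / 2.0
    return LaplacianMatrix(L=L, degrees=deg, kept=kept)


def top_eigenvectors(lap: LaplacianMatrix, k: int,
                     metric: str = "") -> SpectralEmbedding:
    """Eigenvectors of the k algebraically largest Laplacian eigenvalues.

    Deterministic: full symmetric eigendecomposition, eigenvalues sorted
    descending, each column's sign fixed so its largest-magnitude entry is
    positive.
    """
    n = lap.n
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n (got k={k}, n={n})")
    w, v = np.linalg.eigh(lap.L)
    order = np.argsort(w)[::-1]
    w = w[order][:k]
    v = v[:, order][:, :k]
    for c in range(k):
        j = np.argmax(np.abs(v[:, c]))
        if v[j, c] < 0:
            v[:, c] = -v[:, c]
    return SpectralEmbedding(X=v, eigenvalues=w, metric=metric, kept=lap.kept)


def embed(m: ContactMatrix, metric: str, k: int) -> SpectralEmbedding:
    """Convenience: adjacency -> Laplacian -> top-k eigenvectors."""
    return top_eigenvectors(laplacian(build_adjacency(m, metric)), k,
                            metric=metric)


def _laplacian_eigenvalues(a: np.ndarray) -> np.ndarray:
    deg = a.sum(axis=1)
    keep = deg > 0
    a = a[np.ix_(keep, keep)]
    inv_sqrt = 1.0 / np.sqrt(deg[keep])
    L = a * np.outer(inv_sqrt, inv_sqrt)
    return np.sort(np.linalg.eigvalsh((L + L.T) / 2.0))[::-1]


def suggest_max_k(g: SimilarityGraph, n_perm: int = 20, alpha: float = 0.05,
                  seed: int = 0) -> int:
    """Upper bound on the cluster count via randomized-graph comparison.

    The off-diagonal upper-triangle weights are shuffled (preserving the
    weight multiset) to form null graphs; the suggested bound is the
    largest m whose observed m-th Laplacian eigenvalue exceeds the
    (1-alpha) null quantile of that eigenvalue.  A structureless graph
    yields 1.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    rng = np.random.default_rng(seed)
    n = g.n
    obs = _laplacian_eigenvalues(g.adjacency)
    iu = np.triu_indices(n, k=1)
    weights = g.adjacency[iu]
    null = np.full((n_perm, n), np.nan)
    for p in range(n_perm):
        perm = rng.permutation(len(weights))
        a = np.zeros((n, n))
        a[iu] = weights[perm]
        a = a + a.T
        ev = _laplacian_eigenvalues(a)
        null[p, :len(ev)] = ev
    best = 1
    for m in range(2, len(obs) + 1):
        col = null[:, m - 1]
        col = col[~np.isnan(col)]
        if len(col) == 0:
            break
        q = np.quantile(col, 1.0 - alpha)
        if obs[m - 1] > q:
            best = m
        else:
            # the run of elevated eigenvalues ends here; deeper spectrum
            # positions exceed the null only by chance
            break
    return best


def zero_cis(m: ContactMatrix) -> ContactMatrix:
    """Zero all intra-chromosomal entries, keeping trans contacts only."""
    chroms = m.bins.chroms
    same = chroms[:, None] == chroms[None, :]
    counts = np.where(same, 0.0, m.counts)
    return ContactMatrix(m.bins, counts, normalized=m.normalized)
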