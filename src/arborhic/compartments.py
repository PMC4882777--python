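"""A/B compartment calling and partition-agreement statistics.

Compartments are called per chromosome from the raw (pre-ICE) counts:
contact counts are divided by the genome-wide mean contact count at each
genomic distance (observed / expected), the Spearman correlation matrix of
the O/E columns is computed, and the sign of its first principal component
splits the chromosome into two compartments.  Nothing in the matrix
itself identifies which sign is the active compartment, so orientation is
anchored to group size (the larger group is "A"); callers may re-anchor
with an activity track.

``f_score_partitions`` and ``rand_index`` quantify agreement between a
clustering and a compartment split (or any two partitions) through
co-clustered pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .bins_io import ContactMatrix
from .cluster import ClusterAssignment

logger = logging.getLogger(__name__)


@dataclass
class ExpectedProfile:
    """Genome-wide mean contact count per intra-chromosomal bin distance."""

    distances: np.ndarray
    means: np.ndarray

    def lookup(self, s: int) -> float:
        pos = np.searchsorted(self.distances, s)
        if pos < len(self.distances) and self.distances[pos] == s:
            return float(self.means[pos])
        raise KeyError(f"no expected value at distance {s}")


@dataclass
class CompartmentLabels:
    """Per-bin A/B labels for one chromosome plus the PC1 values."""

    labels: np.ndarray  # 'A' or 'B'
    pc1: np.ndarray

    def as_assignment(self) -> ClusterAssignment:
        return ClusterAssignment((self.labels == "B").astype(int), k=2,
                                 method="compartments")


def expected_by_distance(m: ContactMatrix) -> ExpectedProfile:
    """Mean contact count over all intra-chromosomal pairs at each bin
    distance, pooled genome-wide."""
    chroms = m.bins.chroms
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for chrom in pd_unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        sub = m.counts[np.ix_(idx, idx)]
        nc = len(idx)
        for s in range(nc):
            diag = np.diagonal(sub, offset=s)
            sums[s] = sums.get(s, 0.0) + diag.sum()
            counts[s] = counts.get(s, 0) + len(diag)
    distances = np.array(sorted(sums))
    means = np.array([sums[s] / counts[s] for s in distances])
    return ExpectedProfile(distances=distances, means=means)


def pd_unique(values: np.ndarray) -> np.ndarray:
    """Unique values in order of first appearance."""
    _, first = np.unique(values, return_index=True)
    return values[np.sort(first)]


def observed_over_expected(m_chrom: ContactMatrix,
                           e: ExpectedProfile) -> np.ndarray:
    """Divide each count by the expected count at its bin distance.

    Distances with zero expected value yield 0 (with a warning) rather
    than NaN.
    """
    n = m_chrom.n
    idx = np.arange(n)
    s = np.abs(idx[:, None] - idx[None, :])
    exp = np.empty((n, n))
    lut = dict(zip(e.distances.tolist(), e.means.tolist()))
    for dist in np.unique(s):
        if dist not in lut:
            raise KeyError(f"expected profile lacks distance {dist}")
        exp[s == dist] = lut[dist]
    zero = exp == 0
    if zero.any():
        logger.warning("%d cells at zero-expected distances set to 0",
                       int(zero.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(zero, 0.0, m_chrom.counts / np.where(zero, 1.0, exp))
    return oe


def compartment_pc1(oe: np.ndarray) -> CompartmentLabels:
    """Split a chromosome by the sign of PC1 of the Spearman correlation
    matrix of the O/E columns; the larger sign group is labeled A."""
    oe = np.asarray(oe, dtype=float)
    n = oe.shape[0]
    if n < 3:
        raise ValueError("need at least 3 bins")
    ranked = np.apply_along_axis(rankdata, 0, oe)  # rank within each column
    sd = ranked.std(axis=0)
    constant = sd == 0
    safe = ranked.copy()
    safe[:, constant] = np.arange(n)[:, None]
    corr = np.corrcoef(safe, rowvar=False)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    if not np.isfinite(corr).all():
        raise ValueError("degenerate correlation matrix")
    w, v = np.linalg.eigh(corr)
    pc1 = v[:, -1] * np.sqrt(max(w[-1], 0.0))
    # orient so the larger group is nonnegative ("A")
    if (pc1 >= 0).sum() < (pc1 < 0).sum():
        pc1 = -pc1
    labels = np.where(pc1 >= 0, "A", "B")
    return CompartmentLabels(labels=labels, pc1=pc1)


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int, int]:
    """(same-in-a, same-in-b, same-in-both, different-in-both) pair counts,
    computed from the contingency table."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 elements")
    ua, ai = np.unique(a, return_inverse=True)
    ub, bi = np.unique(b, return_inverse=True)
    ct = np.zeros((len(ua), len(ub)), dtype=np.int64)
    np.add.at(ct, (ai, bi), 1)
    comb = lambda x: x * (x - 1) // 2
    s = int(comb(ct.sum(axis=1)).sum())
    c = int(comb(ct.sum(axis=0)).sum())
    o = int(comb(ct).sum())
    total = comb(n)
    bboth = total - s - c + o
    return s, c, o, int(bboth)


def f_score_partitions(a, b) -> float:
    """F score over co-clustered pairs: precision o/s against partition a,
    recall o/c against partition b."""
    la = a.labels if hasattr(a, "labels") else np.asarray(a)
    lb = b.labels if hasattr(b, "labels") else np.asarray(b)
    s, c, o, _ = _pair_counts(la, lb)
    if s == 0 or c == 0:
        return 0.0
    p = o / s
    r = o / c
    if p + r == 0:
        return 0.0
    return 2 * p * r / (p + r)


def rand_index(a, b) -> float:
    """(co-clustered-in-both + separated-in-both) / C(n, 2)."""
    la = a.labels if hasattr(a, "labels") else np.asarray(a)
    lb = b.labels if hasattr(b, "labels") else np.asarray(b)
    _, _, o, bboth = _pair_counts(la, lb)
    n = len(la)
    return (o + bboth) / (n * (n - 1) // 2)
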