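"""Cross-dataset cluster comparison and conservation statistics.

Given two clusterings over a common universe of (orthologously) mapped
regions, the overlap of every cluster pair is scored with an upper-tail
hypergeometric test; the matrix of -log10 p values supports:

* a conservation score — sum of diagonal minus sum of off-diagonal
  entries (large when matched cluster IDs overlap far beyond chance);
* Hungarian matching of cluster IDs for independently produced
  clusterings, which have no shared ID space;
* counting of significant off-diagonal "divergence" events between
  high- and low-activity cluster classes.

``conserved_core`` extracts the regions that keep one cluster ID across
every dataset of a multi-task fit, and ``enrichment_ratio`` is the simple
fold enrichment (o/N)/(K/M) of an overlap over its background rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import hypergeom

from .cluster import ClusterAssignment

logger = logging.getLogger(__name__)

NEGLOG_CAP = 300.0


@dataclass
class OverlapMatrix:
    """-log10 hypergeometric overlap p-values between two clusterings,
    plus the underlying counts."""

    neglog_p: np.ndarray
    overlap_counts: np.ndarray
    sizes_a: np.ndarray
    sizes_b: np.ndarray
    universe: int

    @property
    def k(self) -> int:
        return self.neglog_p.shape[0]


def _restrict(a: ClusterAssignment, b: ClusterAssignment, mapping):
    """Labels of both clusterings over the mapped universe.

    ``mapping`` is an OrthologyMap linking a's bins (h side) to b's bins
    (m side), or None for a shared bin universe.
    """
    if mapping is None:
        if a.n != b.n:
            raise ValueError("clusterings differ in size with no mapping")
        return a.labels, b.labels
    pairs = mapping.pairs
    if not pairs:
        raise ValueError("empty mapped universe")
    ai = np.array([h for h, _ in pairs])
    bi = np.array([m for _, m in pairs])
    return a.labels[ai], b.labels[bi]


def overlap_matrix(a: ClusterAssignment, b: ClusterAssignment,
                   mapping=None) -> OverlapMatrix:
    """Upper-tail hypergeometric overlap of every (a-cluster, b-cluster)
    pair over the mapped universe M: p = P(X >= o) with |cluster i|
    successes and |cluster j| draws; entries are -log10 p capped at 300."""
    la, lb = _restrict(a, b, mapping)
    m_universe = len(la)
    counts = np.zeros((a.k, b.k), dtype=np.int64)
    np.add.at(counts, (la, lb), 1)
    sizes_a = counts.sum(axis=1)
    sizes_b = counts.sum(axis=0)
    neglog = np.zeros((a.k, b.k))
    for i in range(a.k):
        for j in range(b.k):
            o = counts[i, j]
            # P(X >= o); sf(o-1) is the exact upper tail
            p = hypergeom.sf(o - 1, m_universe, sizes_a[i], sizes_b[j])
            p = min(max(p, 0.0), 1.0)
            if p <= 0:
                neglog[i, j] = NEGLOG_CAP
            else:
                neglog[i, j] = min(max(-np.log10(p), 0.0), NEGLOG_CAP)
    return OverlapMatrix(neglog_p=neglog, overlap_counts=counts,
                         sizes_a=sizes_a, sizes_b=sizes_b,
                         universe=m_universe)


def conservation_score(om: OverlapMatrix) -> float:
    """Sum of diagonal minus sum of off-diagonal -log10 p entries."""
    if om.neglog_p.shape[0] != om.neglog_p.shape[1]:
        raise ValueError("conservation score needs a square overlap matrix")
    diag = np.trace(om.neglog_p)
    return float(2 * diag - om.neglog_p.sum())


def _overlap_counts(a: ClusterAssignment, b: ClusterAssignment,
                    mapping, k: int) -> np.ndarray:
    la, lb = _restrict(a, b, mapping)
    ct = np.zeros((k, k), dtype=np.int64)
    np.add.at(ct, (la, lb), 1)
    return ct


def hungarian_match(a: ClusterAssignment, b: ClusterAssignment,
                    mapping=None) -> np.ndarray:
    """Permutation relabeling b's cluster IDs to maximise the total
    overlap count with a's clusters.

    Returns ``perm`` with ``perm[j]`` the a-cluster assigned to b-cluster
    j; apply as ``perm[b.labels]``.  Among equally optimal matchings the
    lexicographically smallest permutation is returned.
    """
    k = max(a.k, b.k)
    ct = _overlap_counts(a, b, mapping, k).astype(float)
    cost = -ct.T  # rows: b clusters, cols: a clusters
    row, col = linear_sum_assignment(cost)
    best_total = -cost[row, col].sum()
    # fix rows one at a time to the smallest column that still admits an
    # optimal completion -> lexicographically smallest optimal permutation
    perm = np.full(k, -1, dtype=int)
    fixed_cost = cost.copy()
    for r in range(k):
        for c in sorted(set(range(k)) - set(perm[:r])):
            trial = fixed_cost.copy()
            big = abs(trial).sum() + 1.0
            trial[r, :] = big
            trial[:, c] = big
            trial[r, c] = fixed_cost[r, c]
            rr, cc = linear_sum_assignment(trial)
            if -trial[rr, cc].sum() >= best_total - 1e-9:
                perm[r] = c
                fixed_cost = trial
                break
    return perm


def conserved_core(assignments: dict[str, ClusterAssignment],
                   tuples: dict[str, np.ndarray], k: int):
    """Regions keeping one cluster ID across every dataset.

    ``assignments`` hold tuple-level labels (one per tuple, aligned across
    leaves in a shared ID space, e.g. a multi-task fit).  Returns
    (core_lists, fractions): per cluster, the tuple indices in the core,
    and per leaf the fraction of its cluster members that are core.
    """
    leaves = list(assignments)
    labs = np.stack([assignments[leaf].labels for leaf in leaves])
    agree = (labs == labs[0]).all(axis=0)
    core_lists = {c: np.flatnonzero(agree & (labs[0] == c))
                  for c in range(k)}
    fractions = {}
    for leaf in leaves:
        sizes = np.bincount(assignments[leaf].labels, minlength=k)
        fr = np.zeros(k)
        for c in range(k):
            fr[c] = len(core_lists[c]) / sizes[c] if sizes[c] else 0.0
        fractions[leaf] = fr
    return core_lists, fractions


def enrichment_ratio(o: int, n: int, k: int, m: int) -> float:
    """Fold enrichment (o/n) / (k/m): overlap rate over background rate."""
    if n == 0 or k == 0:
        raise ValueError("n and k must be positive")
    return (o / n) / (k / m)


def transition_counts(om: OverlapMatrix, act_a: dict[int, str],
                      act_b: dict[int, str],
                      threshold: float = 2.0) -> np.ndarray:
    """Count significant off-diagonal overlaps between activity classes.

    Off-diagonal cells with -log10 p >= threshold are binned into a 2x2
    table indexed (row-class, column-class) with classes (high, low);
    clusters mapped to 'unclassified' are excluded with a warning.
    """
    classes = ("high", "low")
    out = np.zeros((2, 2), dtype=int)
    skipped = False
    for i in range(om.neglog_p.shape[0]):
        for j in range(om.neglog_p.shape[1]):
            if i == j:
                continue
            ca = act_a.get(i, "unclassified")
            cb = act_b.get(j, "unclassified")
            if ca not in classes or cb not in classes:
                skipped = True
                continue
            if om.neglog_p[i, j] >= threshold:
                out[classes.index(ca), classes.index(cb)] += 1
    if skipped:
        logger.warning("unclassified clusters excluded from transition counts")
    return out
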