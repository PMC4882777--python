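"""Cluster-quality criteria and cross-method ranking.

Five criteria are used to compare clusterings of the same Hi-C map:

* Davies-Bouldin index (DBI, lower better), with the within- and
  between-cluster scatters defined as mean pairwise distances because not
  every method provides a centroid;
* silhouette index (SI, higher better), averaged per cluster and then over
  clusters;
* delta contact count (higher better): mean over clusters of in-cluster
  minus out-of-cluster average log contact;
* number of clusters enriched for at least one 1D genomic signal, via a
  one-sided two-sample KS test of "inside stochastically larger";
* a one-way ANOVA score, the sum over signals of -log10 p of the F test
  of signal means across clusters.

``rank_methods`` then ranks each method 1..m per criterion (ties get mean
ranks) and averages ranks across criteria.
"""

from __future__ import annotations

import logging
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bins_io import SignalTrack
from .cluster import ClusterAssignment, DistanceMatrix

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300


def _mean_within(d: np.ndarray, members: np.ndarray) -> float:
    """Mean pairwise distance within a cluster; 0 for singletons."""
    if len(members) < 2:
        logger.warning("singleton cluster: within-distance set to 0")
        return 0.0
    sub = d[np.ix_(members, members)]
    m = len(members)
    return sub.sum() / (m * (m - 1))


def _mean_between(d: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    return d[np.ix_(a, b)].mean()


def dbi(d: DistanceMatrix, a: ClusterAssignment) -> float:
    """Davies-Bouldin index with mean-pairwise-distance scatters.

    DBI = (1/k) sum_i max_{j != i} (dbar_i + dbar_j) / d_ij.
    """
    if a.k < 2:
        raise ValueError("DBI undefined for a single cluster")
    members = [a.members(c) for c in range(a.k)]
    dbar = [_mean_within(d.values, m) for m in members]
    total = 0.0
    for i in range(a.k):
        best = -np.inf
        for j in range(a.k):
            if i == j:
                continue
            between = _mean_between(d.values, members[i], members[j])
            if between == 0:
                ratio = 0.0 if (dbar[i] + dbar[j]) == 0 else np.inf
            else:
                ratio = (dbar[i] + dbar[j]) / between
            best = max(best, ratio)
        total += best
    return total / a.k


def silhouette(d: DistanceMatrix, a: ClusterAssignment) -> float:
    """Silhouette index as the mean over clusters of per-cluster mean s_j.

    s_j = (b_j - a_j) / max(a_j, b_j) with a_j the mean distance to own
    cluster mates and b_j the mean distance to the closest other cluster;
    degenerate 0/0 cases contribute 0.
    """
    if a.k < 2:
        raise ValueError("silhouette undefined for a single cluster")
    members = [a.members(c) for c in range(a.k)]
    per_cluster = []
    for c in range(a.k):
        svals = []
        for j in members[c]:
            own = members[c][members[c] != j]
            aj = d.values[j, own].mean() if len(own) else 0.0
            bj = min(
                d.values[j, members[o]].mean()
                for o in range(a.k) if o != c and len(members[o])
            )
            denom = max(aj, bj)
            svals.append(0.0 if denom == 0 else (bj - aj) / denom)
        if svals:
            per_cluster.append(float(np.mean(svals)))
    return float(np.mean(per_cluster))


def delta_contact(logC: np.ndarray, a: ClusterAssignment) -> float:
    """Mean over clusters of (within-cluster - out-of-cluster) average log
    contact count; self pairs excluded from the within average."""
    logC = np.asarray(logC, dtype=float)
    total = 0.0
    for c in range(a.k):
        inside = a.members(c)
        outside = np.flatnonzero(a.labels != c)
        if len(inside) < 2:
            logger.warning("cluster %d has < 2 members: in-average set to 0", c)
            in_mean = 0.0
        else:
            sub = logC[np.ix_(inside, inside)]
            m = len(inside)
            in_mean = (sub.sum() - np.trace(sub)) / (m * (m - 1))
        out_mean = (logC[np.ix_(inside, outside)].mean()
                    if len(inside) and len(outside) else 0.0)
        total += in_mean - out_mean
    return total / a.k


def _ks_dminus(inside: np.ndarray, outside: np.ndarray) -> float:
    """D- = max_x (F_out(x) - F_in(x)), the one-sided KS statistic for
    'inside stochastically larger'."""
    grid = np.concatenate([inside, outside])
    f_in = np.searchsorted(np.sort(inside), grid, side="right") / len(inside)
    f_out = np.searchsorted(np.sort(outside), grid, side="right") / len(outside)
    return max(0.0, (f_out - f_in).max())


def ks_enrichment_pvalue(inside: np.ndarray, outside: np.ndarray,
                         method: str = "exact") -> float:
    """One-sided two-sample KS p-value for "inside stochastically larger".

    ``method='exact'`` (default) computes the exact conditional
    P(D- >= observed) under uniform relabeling of the pooled sample, by
    dynamic programming over the lattice of partial ECDFs with
    hypergeometric transition kernels.  This handles ties correctly (count
    data is heavily tied), matches the permutation null by construction,
    and reduces to the classical exact one-sided two-sample KS p-value for
    continuous data.  ``method='asymptotic'`` uses the large-sample bound
    exp(-2 m n D^2 / (m + n)), which is conservative at moderate n.
    """
    inside = np.asarray(inside, dtype=float)
    outside = np.asarray(outside, dtype=float)
    inside = inside[~np.isnan(inside)]
    outside = outside[~np.isnan(outside)]
    if len(inside) < 2 or len(outside) < 2:
        return 1.0
    m, n = len(inside), len(outside)
    d_minus = _ks_dminus(inside, outside)
    if method == "asymptotic":
        return float(np.exp(-2.0 * m * n * d_minus ** 2 / (m + n)))
    if method != "exact":
        raise ValueError("method must be 'exact' or 'asymptotic'")
    pooled = np.concatenate([inside, outside])
    vals, counts = np.unique(pooled, return_counts=True)
    # DP over distinct values: state = #inside assigned so far; survive
    # while every partial D- stays strictly below the observed statistic
    probs = np.zeros(m + 1)
    probs[0] = 1.0
    used = 0
    total = m + n
    iarr = np.arange(m + 1)
    for c in counts:
        cmax = min(int(c), m)
        t = np.arange(cmax + 1)
        with np.errstate(invalid="ignore"):
            w = stats.hypergeom.pmf(t[None, :], total - used,
                                    (m - iarr)[:, None], int(c))
        w = np.nan_to_num(w)  # impossible states carry zero mass anyway
        contrib = probs[:, None] * w
        new = np.zeros(m + 1)
        for tt in range(cmax + 1):
            new[tt:] += contrib[:m + 1 - tt, tt]
        used += int(c)
        d = (used - iarr) / n - iarr / m
        new = np.where(d >= d_minus - 1e-12, 0.0, new)
        probs = new
    return float(min(max(1.0 - probs.sum(), 0.0), 1.0))


def ks_enrichment(s: SignalTrack, a: ClusterAssignment,
                  alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Per-cluster enrichment of a signal: p-values and enriched flags."""
    pvals = np.ones(a.k)
    for c in range(a.k):
        inside = s.values[a.labels == c]
        outside = s.values[a.labels != c]
        pvals[c] = ks_enrichment_pvalue(inside, outside)
    return pvals, pvals < alpha


def count_enriched_clusters(signals: Sequence[SignalTrack],
                            a: ClusterAssignment,
                            alpha: float = 0.05) -> int:
    """Number of clusters enriched (one-sided KS, p < alpha) for at least
    one of the given signals."""
    enriched_any = np.zeros(a.k, dtype=bool)
    for s in signals:
        _, flags = ks_enrichment(s, a, alpha=alpha)
        enriched_any |= flags
    return int(enriched_any.sum())


def anova_score(signals: Sequence[SignalTrack],
                a: ClusterAssignment) -> float:
    """Sum over signals of -log10 p from a one-way F test of the signal
    across clusters; p is floored at 1e-300, constant signals contribute 0."""
    score = 0.0
    for s in signals:
        groups = []
        for c in range(a.k):
            v = s.values[a.labels == c]
            v = v[~np.isnan(v)]
            if len(v) >= 2:
                groups.append(v)
        if len(groups) < 2:
            continue
        if all(np.ptp(g) == 0 for g in groups) and \
                np.ptp(np.concatenate(groups)) == 0:
            continue  # constant signal, p = 1
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.f_oneway(*groups)
        if np.isnan(p):
            continue
        score += -np.log10(max(p, P_FLOOR))
    return float(score)


def rank_methods(table: pd.DataFrame,
                 higher_better: dict[str, bool]) -> pd.Series:
    """Average rank per method across criteria (rank 1 = best, ties get
    the mean of the tied positions)."""
    if table.isna().any().any():
        raise ValueError("score table has missing cells")
    ranks = pd.DataFrame(index=table.index, columns=table.columns,
                         dtype=float)
    for col in table.columns:
        asc = not higher_better[col]
        ranks[col] = table[col].rank(ascending=asc, method="average")
    return ranks.mean(axis=1)


def permutation_null(metric_fn: Callable[[ClusterAssignment], float],
                     a: ClusterAssignment, n_perm: int = 100,
                     seed: int = 0, higher_better: bool = True) -> float:
    """Permutation p-value for a label-dependent cluster metric.

    Labels are shuffled uniformly; p = (1 + #{perm >= obs}) / (1 + n_perm)
    for higher-better metrics (reversed otherwise).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    obs = metric_fn(a)
    hits = 0
    for _ in range(n_perm):
        perm = ClusterAssignment(rng.permutation(a.labels), k=a.k)
        val = metric_fn(perm)
        if (val >= obs) if higher_better else (val <= obs):
            hits += 1
    return (1 + hits) / (1 + n_perm)
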