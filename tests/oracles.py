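"""Independent brute-force oracles used by the acceptance checks.

Every function here evaluates its statistic by direct enumeration of the
defining formula (pair loops, exact rational tail sums), sharing no code
with the package implementations it certifies.
"""

import itertools
from fractions import Fraction
from math import comb

import numpy as np


def dbi_brute(d, labels, k):
    members = [np.flatnonzero(labels == c) for c in range(k)]
    dbar = []
    for c in range(k):
        pairs = list(itertools.combinations(members[c], 2))
        dbar.append(np.mean([d[i, j] for i, j in pairs]) if pairs else 0.0)
    total = 0.0
    for i in range(k):
        ratios = []
        for j in range(k):
            if i == j:
                continue
            between = np.mean([d[p, q] for p in members[i]
                               for q in members[j]])
            ratios.append((dbar[i] + dbar[j]) / between)
        total += max(ratios)
    return total / k


def silhouette_brute(d, labels, k):
    members = [np.flatnonzero(labels == c) for c in range(k)]
    per_cluster = []
    for c in range(k):
        svals = []
        for j in members[c]:
            others = [x for x in members[c] if x != j]
            aj = np.mean([d[j, x] for x in others]) if others else 0.0
            bj = min(np.mean([d[j, x] for x in members[o]])
                     for o in range(k) if o != c)
            svals.append((bj - aj) / max(aj, bj) if max(aj, bj) > 0 else 0.0)
        per_cluster.append(np.mean(svals))
    return np.mean(per_cluster)


def delta_brute(logC, labels, k):
    n = len(labels)
    total = 0.0
    for c in range(k):
        inside = [i for i in range(n) if labels[i] == c]
        outside = [i for i in range(n) if labels[i] != c]
        in_pairs = [logC[i, j] for i in inside for j in inside if i != j]
        out_pairs = [logC[i, j] for i in inside for j in outside]
        total += (np.mean(in_pairs) if in_pairs else 0.0) - \
                 (np.mean(out_pairs) if out_pairs else 0.0)
    return total / k


def f_brute(la, lb):
    n = len(la)
    s = c_ = o = 0
    for i, j in itertools.combinations(range(n), 2):
        sa = la[i] == la[j]
        sb = lb[i] == lb[j]
        s += sa
        c_ += sb
        o += sa and sb
    if s == 0 or c_ == 0:
        return 0.0
    p, r = o / s, o / c_
    return 2 * p * r / (p + r) if p + r else 0.0


def rand_brute(la, lb):
    n = len(la)
    agree = sum((la[i] == la[j]) == (lb[i] == lb[j])
                for i, j in itertools.combinations(range(n), 2))
    return agree / (n * (n - 1) // 2)


def hypergeom_tail_exact(o, M, K, N):
    """Exact upper-tail P(X >= o) as a rational number."""
    total = Fraction(0)
    for x in range(o, min(K, N) + 1):
        total += Fraction(comb(K, x) * comb(M - K, N - x), comb(M, N))
    return total
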