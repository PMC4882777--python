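import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from arborhic import evaluate as ev, simulate as sim
from arborhic.bins_io import SignalTrack, make_bins
from arborhic.cluster import ClusterAssignment, DistanceMatrix


def random_distance(n, rng):
    d = rng.uniform(0.1, 2.0, (n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, "random")


# --- independent brute-force oracles -----------------------------------


def dbi_brute(d, labels, k):
    dbar = []
    members = [np.flatnonzero(labels == c) for c in range(k)]
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
    total = 0.0
    n = len(labels)
    for c in range(k):
        inside = [i for i in range(n) if labels[i] == c]
        outside = [i for i in range(n) if labels[i] != c]
        in_pairs = [logC[i, j] for i in inside for j in inside if i != j]
        out_pairs = [logC[i, j] for i in inside for j in outside]
        total += (np.mean(in_pairs) if in_pairs else 0.0) - \
                 (np.mean(out_pairs) if out_pairs else 0.0)
    return total / k


def balanced_labels(n, k, rng):
    lab = np.arange(n) % k
    return rng.permutation(lab)


class TestDbi:
    def test_zero_internal_distance_gives_zero(self):
        d = np.ones((4, 4))
        d[0, 1] = d[1, 0] = 0.0
        d[2, 3] = d[3, 2] = 0.0
        np.fill_diagonal(d, 0.0)
        a = ClusterAssignment([0, 0, 1, 1], k=2)
        assert ev.dbi(DistanceMatrix(d, "t"), a) == 0.0

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            d = random_distance(12, rng)
            labels = balanced_labels(12, 3, rng)
            a = ClusterAssignment(labels, k=3)
            assert ev.dbi(d, a) == pytest.approx(
                dbi_brute(d.values, labels, 3), abs=1e-12)

    def test_merging_distant_clusters_increases_dbi(self, rng):
        # three tight groups far apart; merging two of them into one
        # cluster inflates the within scatter
        n = 12
        d = np.full((n, n), 0.01)
        groups = [range(0, 4), range(4, 8), range(8, 12)]
        for ga, gb in itertools.combinations(range(3), 2):
            for i in groups[ga]:
                for j in groups[gb]:
                    d[i, j] = d[j, i] = 5.0
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(d, "t")
        good = ClusterAssignment([0] * 4 + [1] * 4 + [2] * 4, k=3)
        merged = ClusterAssignment([0] * 8 + [1] * 4, k=2)
        assert ev.dbi(dm, merged) > ev.dbi(dm, good)

    def test_single_cluster_rejected(self, rng):
        d = random_distance(6, rng)
        with pytest.raises(ValueError):
            ev.dbi(d, ClusterAssignment([0] * 6, k=1))


class TestSilhouette:
    def test_maximal_separation_gives_one(self):
        d = np.ones((6, 6))
        d[:3, :3] = 0.0
        d[3:, 3:] = 0.0
        np.fill_diagonal(d, 0.0)
        a = ClusterAssignment([0] * 3 + [1] * 3, k=2)
        assert ev.silhouette(DistanceMatrix(d, "t"), a) == 1.0

    def test_identical_points_give_zero(self):
        d = np.zeros((6, 6))
        a = ClusterAssignment([0, 0, 0, 1, 1, 1], k=2)
        assert ev.silhouette(DistanceMatrix(d, "t"), a) == 0.0

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            d = random_distance(12, rng)
            labels = balanced_labels(12, 3, rng)
            a = ClusterAssignment(labels, k=3)
            assert ev.silhouette(d, a) == pytest.approx(
                silhouette_brute(d.values, labels, 3), abs=1e-12)


class TestDeltaContact:
    def test_constant_matrix_zero(self):
        logC = np.full((8, 8), 3.0)
        a = ClusterAssignment([0] * 4 + [1] * 4, k=2)
        assert ev.delta_contact(logC, a) == pytest.approx(0.0, abs=1e-12)

    def test_two_block_closed_form(self):
        b_val, a_val = 5.0, 1.0
        logC = np.full((10, 10), a_val)
        logC[:5, :5] = b_val
        logC[5:, 5:] = b_val
        a = ClusterAssignment([0] * 5 + [1] * 5, k=2)
        assert ev.delta_contact(logC, a) == pytest.approx(b_val - a_val)

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            c = rng.uniform(0, 4, (12, 12))
            logC = (c + c.T) / 2
            labels = balanced_labels(12, 3, rng)
            a = ClusterAssignment(labels, k=3)
            assert ev.delta_contact(logC, a) == pytest.approx(
                delta_brute(logC, labels, 3), abs=1e-12)


class TestKsEnrichment:
    def test_identical_samples_not_enriched(self):
        v = np.concatenate([np.arange(20.0), np.arange(20.0)])
        bins = make_bins({"chr1": 40 * 10}, 10)
        s = SignalTrack(bins, v)
        a = ClusterAssignment([0] * 20 + [1] * 20, k=2)
        _, flags = ev.ks_enrichment(s, a)
        assert not flags.any()

    def test_large_upward_shift_detected(self, rng):
        inside = rng.normal(3, 1, 50)
        outside = rng.normal(0, 1, 50)
        p = ev.ks_enrichment_pvalue(inside, outside)
        assert p < 1e-6

    def test_downward_shift_not_flagged(self, rng):
        inside = rng.normal(-3, 1, 50)
        outside = rng.normal(0, 1, 50)
        assert ev.ks_enrichment_pvalue(inside, outside) > 0.5

    def test_exact_matches_scipy_on_continuous_data(self, rng):
        for _ in range(10):
            i = rng.normal(0.3, 1, 30)
            o = rng.normal(0, 1, 40)
            ours = ev.ks_enrichment_pvalue(i, o)
            ref = stats.ks_2samp(i, o, alternative="less",
                                 method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_exact_agrees_with_permutation_under_ties(self, rng):
        i = rng.poisson(10, 60).astype(float)
        o = rng.poisson(9, 80).astype(float)
        p = ev.ks_enrichment_pvalue(i, o)
        obs = ev._ks_dminus(i, o)
        pooled = np.concatenate([i, o])
        hits = 0
        n_perm = 3000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if ev._ks_dminus(perm[:60], perm[60:]) >= obs - 1e-12:
                hits += 1
        assert p == pytest.approx(hits / n_perm, abs=0.02)


class TestCountEnriched:
    def test_no_signals_gives_zero(self):
        a = ClusterAssignment([0, 1] * 10, k=2)
        assert ev.count_enriched_clusters([], a) == 0

    def test_planted_enrichment_counted_once(self, rng):
        bins = make_bins({"chr1": 250 * 10}, 10)
        labels = np.repeat(np.arange(5), 50)
        a = ClusterAssignment(labels, k=5)
        s1 = sim.simulate_signal(labels, [1, 3], bins, effect=3.0, seed=1)
        s2 = sim.simulate_signal(labels, [1], bins, effect=3.0, seed=2)
        # cluster 1 is enriched in both signals but counts once
        assert ev.count_enriched_clusters([s1, s2], a) == 2


class TestAnovaScore:
    def test_cluster_linked_signal_scores_high(self, rng):
        bins = make_bins({"chr1": 100 * 10}, 10)
        labels = np.repeat(np.arange(4), 25)
        vals = labels + rng.normal(0, 0.01, 100)
        s = SignalTrack(bins, vals)
        a = ClusterAssignment(labels, k=4)
        assert ev.anova_score([s], a) > 50

    def test_constant_signal_contributes_zero(self):
        bins = make_bins({"chr1": 40 * 10}, 10)
        s = SignalTrack(bins, np.full(40, 2.0))
        a = ClusterAssignment([0, 1] * 20, k=2)
        assert ev.anova_score([s], a) == 0.0

    def test_two_cluster_f_equals_t_squared(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.5, 1, 30)
        f, _ = stats.f_oneway(x, y)
        t, _ = stats.ttest_ind(x, y)
        assert f == pytest.approx(t ** 2, rel=1e-9)


class TestRankMethods:
    def test_basic_ranks(self):
        t = pd.DataFrame({"m": [3.0, 1.0, 2.0]}, index=["a", "b", "c"])
        r = ev.rank_methods(t, {"m": True})
        assert list(r) == [1.0, 3.0, 2.0]

    def test_tie_gets_mean_rank(self):
        t = pd.DataFrame({"m": [5.0, 5.0, 1.0]}, index=["a", "b", "c"])
        r = ev.rank_methods(t, {"m": True})
        assert list(r) == [1.5, 1.5, 3.0]

    def test_matches_sort_based_oracle(self, rng):
        methods = [f"m{i}" for i in range(15)]
        metrics = [f"s{i}" for i in range(5)]
        t = pd.DataFrame(rng.uniform(size=(15, 5)), index=methods,
                         columns=metrics)
        directions = {m: bool(i % 2) for i, m in enumerate(metrics)}
        r = ev.rank_methods(t, directions)
        expect = np.zeros(15)
        for m in metrics:
            vals = t[m].to_numpy()
            key = -vals if directions[m] else vals
            order = stats.rankdata(key, method="average")
            expect += order
        np.testing.assert_allclose(r.to_numpy(), expect / 5)

    def test_mean_of_average_ranks_is_center(self, rng):
        t = pd.DataFrame(rng.uniform(size=(8, 3)),
                         columns=["a", "b", "c"])
        r = ev.rank_methods(t, {"a": True, "b": False, "c": True})
        assert r.mean() == pytest.approx((8 + 1) / 2)

    def test_missing_cell_rejected(self):
        t = pd.DataFrame({"m": [1.0, np.nan]})
        with pytest.raises(ValueError):
            ev.rank_methods(t, {"m": True})


class TestRankProperties:
    @given(st.lists(st.floats(min_value=-100, max_value=100,
                              allow_nan=False), min_size=2, max_size=12))
    @settings(derandomize=True, max_examples=50)
    def test_rank_mean_is_center_for_any_scores(self, scores):
        t = pd.DataFrame({"m": scores})
        r = ev.rank_methods(t, {"m": True})
        assert r.mean() == pytest.approx((len(scores) + 1) / 2)
        assert r.min() >= 1 and r.max() <= len(scores)


class TestPermutationNull:
    def test_planted_partition_significant(self, rng):
        logC = np.full((40, 40), 1.0)
        logC[:20, :20] = 4.0
        logC[20:, 20:] = 4.0
        truth = ClusterAssignment([0] * 20 + [1] * 20, k=2)
        p = ev.permutation_null(lambda a: ev.delta_contact(logC, a), truth,
                                n_perm=200, seed=1)
        assert p <= 0.01

    def test_deterministic_given_seed(self, rng):
        logC = rng.uniform(0, 2, (20, 20))
        logC = (logC + logC.T) / 2
        a = ClusterAssignment(rng.integers(0, 2, 20), k=2)
        fn = lambda x: ev.delta_contact(logC, x)
        assert (ev.permutation_null(fn, a, n_perm=100, seed=5)
                == ev.permutation_null(fn, a, n_perm=100, seed=5))
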