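import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from arborhic import multitask as mt, simulate as sim
from arborhic.multitask import MultiTaskModel, TaskTree
from arborhic.orthology import OrthologyMap


@pytest.fixture
def four_leaf_tree():
    return TaskTree.from_newick("((A,B),(C,D));")


def gaussian_bundle(tree, k=4, n=500, d=4, diag=0.85, sep=3.0, seed=0):
    trans = sim.make_transitions(tree, k, diag)
    labels = sim.simulate_tree_labels(tree, k, np.full(k, 1 / k), trans, n,
                                      seed=seed)
    leaf_labels = {l: labels[l] for l in tree.leaf_names()}
    obs = sim.simulate_gaussian_observations(leaf_labels, k, d,
                                             separation=sep, seed=seed)
    return labels, obs


class TestTaskTree:
    def test_newick_parse(self):
        t = TaskTree.from_newick("((hESC:0.1,hIMR90:0.1):0.2,(mESC,mCortex));")
        assert t.leaf_names() == ["hESC", "hIMR90", "mESC", "mCortex"]
        assert len(t.nodes()) == 7

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(ValueError):
            TaskTree.from_newick("((A,B),(A,C));")

    def test_preorder_parents_before_children(self, four_leaf_tree):
        nodes = four_leaf_tree.nodes()
        parent = four_leaf_tree.parent_map()
        seen = set()
        for v in nodes:
            if id(v) in parent:
                assert id(parent[id(v)]) in seen
            seen.add(id(v))


class TestBuildRegionTuples:
    def test_complete_tuples(self):
        omap = OrthologyMap([(i, 99 - i) for i in range(100)])
        tuples = mt.build_region_tuples(
            omap, {"A": "h", "B": "h", "C": "m", "D": "m"}, "h", "m")
        assert all(len(v) == 100 for v in tuples.values())
        np.testing.assert_array_equal(tuples["A"], tuples["B"])
        np.testing.assert_array_equal(tuples["C"], 99 - tuples["A"])

    def test_empty_map(self):
        tuples = mt.build_region_tuples(
            OrthologyMap([]), {"A": "h", "B": "m"}, "h", "m")
        assert all(len(v) == 0 for v in tuples.values())

    def test_unmapped_species_rejected(self):
        with pytest.raises(ValueError):
            mt.build_region_tuples(OrthologyMap([(0, 0)]),
                                   {"A": "h", "B": "rat"}, "h", "m")


class TestTreeLoglikelihood:
    def brute_force_ll(self, model, obs):
        """Exhaustive enumeration over all label configurations."""
        tree = model.tree
        nodes = tree.nodes()
        parent = tree.parent_map()
        k = model.k
        n = next(iter(obs.values())).shape[0]
        total = 0.0
        from arborhic.multitask import _log_gaussian
        emis = {v.name: _log_gaussian(obs[v.name], model.means[v.name],
                                      model.variances[v.name])
                for v in nodes if v.is_leaf}
        for t in range(n):
            probs = []
            for config in itertools.product(range(k), repeat=len(nodes)):
                lab = {id(v): config[i] for i, v in enumerate(nodes)}
                lp = np.log(model.pi[lab[id(tree.root)]])
                for v in nodes:
                    if id(v) in parent:
                        tm = model.transitions[v.name]
                        lp += np.log(tm[lab[id(parent[id(v)])], lab[id(v)]])
                    if v.is_leaf:
                        lp += emis[v.name][t, lab[id(v)]]
                probs.append(lp)
            from scipy.special import logsumexp
            total += logsumexp(probs)
        return total

    def test_matches_exhaustive_enumeration(self, rng):
        tree = TaskTree.from_newick("(A,B);")
        k, d = 2, 2
        model = MultiTaskModel(
            tree=tree, k=k,
            pi=np.array([0.3, 0.7]),
            transitions={"A": np.array([[0.8, 0.2], [0.4, 0.6]]),
                         "B": np.array([[0.9, 0.1], [0.25, 0.75]])},
            means={"A": rng.normal(size=(k, d)),
                   "B": rng.normal(size=(k, d))},
            variances={"A": np.full((k, d), 0.5),
                       "B": np.full((k, d), 1.2)},
        )
        obs = {"A": rng.normal(size=(2, d)), "B": rng.normal(size=(2, d))}
        ll = mt.tree_loglikelihood(model, obs)
        assert ll == pytest.approx(self.brute_force_ll(model, obs),
                                   abs=1e-10)

    def test_label_permutation_symmetry(self, four_leaf_tree, rng):
        k, d, n = 3, 2, 20
        branch_names = [v.name for v in four_leaf_tree.nodes()
                        if id(v) in four_leaf_tree.parent_map()]
        model = MultiTaskModel(
            tree=four_leaf_tree, k=k,
            pi=np.array([0.2, 0.3, 0.5]),
            transitions={nm: rng.dirichlet(np.ones(k), size=k)
                         for nm in branch_names},
            means={l: rng.normal(size=(k, d)) for l in "ABCD"},
            variances={l: np.full((k, d), 1.0) for l in "ABCD"},
        )
        obs = {l: rng.normal(size=(n, d)) for l in "ABCD"}
        ll = mt.tree_loglikelihood(model, obs)
        perm = np.array([2, 0, 1])
        ll_perm = mt.tree_loglikelihood(model.permuted(perm), obs)
        assert ll_perm == pytest.approx(ll, abs=1e-10)

    def test_identical_emissions_independent_of_structure(self, rng):
        tree = TaskTree.from_newick("(A,B);")
        k, d = 2, 2
        mean = rng.normal(size=(1, d)).repeat(k, axis=0)
        obs = {"A": rng.normal(size=(5, d)), "B": rng.normal(size=(5, d))}

        def ll_with(pi, ta):
            model = MultiTaskModel(
                tree=tree, k=k, pi=np.asarray(pi),
                transitions={"A": np.asarray(ta),
                             "B": np.array([[0.5, 0.5], [0.5, 0.5]])},
                means={"A": mean, "B": mean},
                variances={"A": np.ones((k, d)), "B": np.ones((k, d))},
            )
            return mt.tree_loglikelihood(model, obs)

        l1 = ll_with([0.5, 0.5], [[0.9, 0.1], [0.1, 0.9]])
        l2 = ll_with([0.2, 0.8], [[0.5, 0.5], [0.6, 0.4]])
        assert l1 == pytest.approx(l2, abs=1e-10)


class TestFit:
    def test_loglik_trace_monotone(self, four_leaf_tree):
        _, obs = gaussian_bundle(four_leaf_tree, n=300, seed=1)
        f = mt.fit(obs, four_leaf_tree, 4, seed=0)
        tr = f.loglik_trace
        assert (np.diff(tr) >= -1e-8 * np.maximum(np.abs(tr[:-1]), 1)).all()

    def test_final_trace_matches_loglikelihood_of_model(self, four_leaf_tree):
        _, obs = gaussian_bundle(four_leaf_tree, n=200, seed=2)
        f = mt.fit(obs, four_leaf_tree, 4, seed=0)
        ll = mt.tree_loglikelihood(f.model, obs)
        assert ll == pytest.approx(f.loglik_trace[-1], rel=1e-9)

    def test_single_leaf_reduces_to_gaussian_mixture(self, rng):
        # one-leaf tree: the model is a plain diagonal-covariance GMM
        tree = TaskTree.from_newick("(A);")
        k, d, n = 3, 2, 300
        labels = rng.integers(0, k, n)
        centers = np.array([[0, 0], [4, 0], [0, 4.0]])
        x = centers[labels] + rng.normal(size=(n, d))
        obs = {"A": x}
        n_iter = 40
        init = mt._initialize(obs, tree, k, seed=0)
        f = mt.fit(obs, tree, k, seed=0, init_model=init, tol=0.0,
                   max_iter=n_iter)

        # independent EM for a diagonal GMM from the same initialization;
        # the tree chain root -> leaf collapses to mixture weights pi @ T
        w = init.pi @ init.transitions["A"]
        mu = init.means["A"].copy()
        var = init.variances["A"].copy()
        from scipy.special import logsumexp
        gmm_trace = []
        for _ in range(n_iter + 1):
            logp = np.stack([
                -0.5 * (((x - mu[c]) ** 2 / var[c]).sum(1)
                        + np.log(var[c]).sum() + d * np.log(2 * np.pi))
                + np.log(w[c]) for c in range(k)], axis=1)
            gmm_trace.append(logsumexp(logp, axis=1).sum())
            g = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
            nk = g.sum(0)
            w = nk / n
            mu = (g.T @ x) / nk[:, None]
            var = np.maximum((g.T @ x ** 2) / nk[:, None] - mu ** 2, 1e-6)
        np.testing.assert_allclose(f.loglik_trace, gmm_trace, rtol=1e-9)

    def test_parameter_recovery(self, four_leaf_tree):
        labels, obs = gaussian_bundle(four_leaf_tree, k=4, n=2000, seed=5)
        f = mt.fit(obs, four_leaf_tree, 4, seed=5)
        for leaf in four_leaf_tree.leaf_names():
            assert adjusted_rand_score(labels[leaf],
                                       f.assignments[leaf].labels) >= 0.9
        diag = np.mean([np.diag(t).mean()
                        for t in f.model.transitions.values()])
        assert diag == pytest.approx(0.85, abs=0.05)

    def test_identity_coupling_forces_identical_labels(self, four_leaf_tree,
                                                       rng):
        # identical observations everywhere + near-identity transitions:
        # every leaf decodes to the same labels
        k, d, n = 3, 2, 100
        x = np.vstack([rng.normal(c * 4, 0.3, size=(n // 2 if c == 0 else
                                                    n - n // 2, d))
                       for c in range(2)])
        obs = {l: x for l in "ABCD"}
        eye = np.full((k, k), 1e-6)
        np.fill_diagonal(eye, 1 - 2e-6)
        branch_names = [v.name for v in four_leaf_tree.nodes()
                        if id(v) in four_leaf_tree.parent_map()]
        trans = {nm: eye.copy() for nm in branch_names}
        model = MultiTaskModel(
            tree=four_leaf_tree, k=k, pi=np.full(k, 1 / k),
            transitions=trans,
            means={l: np.array([[0., 0], [4, 4], [8, 8]]) for l in "ABCD"},
            variances={l: np.ones((k, d)) for l in "ABCD"},
        )
        ll, gamma, _ = mt._message_pass(model, obs)
        decoded = {l: gamma[l].argmax(1) for l in "ABCD"}
        for l in "BCD":
            np.testing.assert_array_equal(decoded["A"], decoded[l])

    def test_posteriors_normalized(self, four_leaf_tree):
        _, obs = gaussian_bundle(four_leaf_tree, n=100, seed=3)
        f = mt.fit(obs, four_leaf_tree, 4, seed=0)
        for post in f.posteriors.values():
            np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)

    def test_k_below_two_rejected(self, four_leaf_tree):
        _, obs = gaussian_bundle(four_leaf_tree, n=50, seed=0)
        with pytest.raises(ValueError):
            mt.fit(obs, four_leaf_tree, 1)


class TestSelectTree:
    def test_recovers_generating_topology(self):
        t_gen = TaskTree.from_newick("((A,B),(C,D));")
        t_alt = TaskTree.from_newick("((A,C),(B,D));")
        k, n, d = 4, 600, 4
        wins = 0
        for rep in range(5):
            bd = {v.name: (0.95 if v.is_leaf else 0.7)
                  for v in t_gen.nodes()[1:]}
            trans = sim.make_transitions(t_gen, k, bd)
            labels = sim.simulate_tree_labels(t_gen, k, np.full(k, 1 / k),
                                              trans, n, seed=rep)
            obs = sim.simulate_gaussian_observations(
                {l: labels[l] for l in t_gen.leaf_names()}, k, d,
                separation=2.0, seed=rep)
            best, _, lls = mt.select_tree([t_gen, t_alt], obs, k,
                                          seeds=(rep,))
            wins += best is t_gen
        assert wins >= 4

    def test_single_candidate_returned(self, four_leaf_tree):
        _, obs = gaussian_bundle(four_leaf_tree, n=100, seed=1)
        best, fit, lls = mt.select_tree([four_leaf_tree], obs, 4, seeds=(0,))
        assert best is four_leaf_tree
        assert len(lls) == 1

    def test_identical_candidates_tie_to_first(self, four_leaf_tree):
        _, obs = gaussian_bundle(four_leaf_tree, n=100, seed=1)
        other = TaskTree.from_newick("((A,B),(C,D));")
        best, _, lls = mt.select_tree([four_leaf_tree, other], obs, 4,
                                      seeds=(0,))
        assert best is four_leaf_tree
        assert lls[0] == pytest.approx(lls[1], rel=1e-9)
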