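"""Tree-structured multi-task Gaussian mixture clustering of Hi-C maps.

Several Hi-C datasets (cell lines and/or species) are clustered
simultaneously.  Each dataset is a leaf of a rooted task tree; each
orthologous region contributes one tuple of spectral-embedding rows, one
per leaf.  The generative model per tuple:

* the root draws a cluster label from a categorical prior pi;
* every child node draws its label from the row of its branch's k x k
  transition matrix indexed by the parent label;
* every leaf emits its embedding row from a diagonal-covariance Gaussian
  indexed by the leaf's label.

High diagonal mass in a branch transition matrix couples the labels of
the datasets it connects, so orthologous regions are favoured to share
cluster assignments to the extent the data supports it.  Inference per
tuple is exact sum-product (upward/downward messages in log space); the
model is fit by EM with closed-form M-steps, and datasets share a single
cluster-ID space rooted at the top node.  Candidate task trees are
compared by their fitted data likelihood.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .cluster import ClusterAssignment

logger = logging.getLogger(__name__)

VAR_FLOOR = 1e-6
LOG_2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# task tree


@dataclass
class TreeNode:
    name: str
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class TaskTree:
    """Rooted tree whose leaves are dataset identifiers.

    Branches are identified by their child node; branch lengths carry no
    meaning here (the model learns one transition matrix per branch).
    """

    root: TreeNode

    def __post_init__(self):
        names = self.leaf_names()
        if len(set(names)) != len(names):
            raise ValueError("duplicate leaf names in task tree")

    def leaves(self) -> list[TreeNode]:
        out = []

        def walk(v):
            if v.is_leaf:
                out.append(v)
            for c in v.children:
                walk(c)

        walk(self.root)
        return out

    def leaf_names(self) -> list[str]:
        return [v.name for v in self.leaves()]

    def nodes(self) -> list[TreeNode]:
        """All nodes in a parent-before-child (preorder) traversal."""
        out = []

        def walk(v):
            out.append(v)
            for c in v.children:
                walk(c)

        walk(self.root)
        return out

    def parent_map(self) -> dict[int, TreeNode]:
        out = {}

        def walk(v):
            for c in v.children:
                out[id(c)] = v
                walk(c)

        walk(self.root)
        return out

    @classmethod
    def from_newick(cls, text: str) -> "TaskTree":
        """Parse a Newick string; branch lengths are ignored (the model is
        parameterized per branch, not by length)."""
        text = text.strip().rstrip(";")
        if ":" in text:
            logger.warning("branch lengths in Newick input are ignored")
        pos = 0
        counter = [0]

        def parse() -> TreeNode:
            nonlocal pos
            node = TreeNode(name="")
            if text[pos] == "(":
                pos += 1
                while True:
                    node.children.append(parse())
                    if text[pos] == ",":
                        pos += 1
                    elif text[pos] == ")":
                        pos += 1
                        break
            m = re.match(r"[^(),:;]*", text[pos:])
            label = m.group(0)
            pos += len(label)
            if text[pos:pos + 1] == ":":
                m2 = re.match(r":[^(),;]*", text[pos:])
                pos += len(m2.group(0))
            if label:
                node.name = label
            elif node.is_leaf:
                raise ValueError("unnamed leaf in Newick input")
            else:
                node.name = f"_internal{counter[0]}"
                counter[0] += 1
            return node

        tree = cls(root=parse())
        if pos != len(text):
            raise ValueError("trailing characters in Newick input")
        return tree


# ---------------------------------------------------------------------------
# region tuples


def build_region_tuples(omap, species_of_leaf: dict[str, str],
                        h_species: str, m_species: str) -> dict[str, np.ndarray]:
    """Bin index per leaf for each orthologous pair.

    Leaves of ``h_species`` take the h-bin index of each pair and leaves
    of ``m_species`` the m-bin index; within a species all leaves share
    the same bin table so they share the index.  Tuples are ordered by
    h-bin index.  Returns {leaf: array of bin indices} with one entry per
    tuple (all arrays equal length).
    """
    unknown = set(species_of_leaf.values()) - {h_species, m_species}
    if unknown:
        raise ValueError(f"leaves of unmapped species: {sorted(unknown)}")
    pairs = sorted(omap.pairs)
    h_idx = np.array([h for h, _ in pairs], dtype=int)
    m_idx = np.array([m for _, m in pairs], dtype=int)
    out = {}
    for leaf, sp in species_of_leaf.items():
        out[leaf] = h_idx if sp == h_species else m_idx
    return out


def tuple_observations(tuples: dict[str, np.ndarray],
                       embeddings: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Row-restrict each leaf's embedding matrix to its tuple bins."""
    return {leaf: np.asarray(embeddings[leaf])[idx]
            for leaf, idx in tuples.items()}


# ---------------------------------------------------------------------------
# model


@dataclass
class MultiTaskModel:
    """Parameters of the tree mixture.

    ``transitions`` maps child-node name -> k x k row-stochastic matrix;
    ``means``/``variances`` map leaf name -> (k, d) arrays (diagonal
    Gaussians).
    """

    tree: TaskTree
    k: int
    pi: np.ndarray
    transitions: dict[str, np.ndarray]
    means: dict[str, np.ndarray]
    variances: dict[str, np.ndarray]

    def validate(self) -> None:
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-10):
            raise ValueError("root prior must sum to 1")
        for name, t in self.transitions.items():
            if t.shape != (self.k, self.k):
                raise ValueError(f"transition {name} has wrong shape")
            if not np.allclose(t.sum(axis=1), 1.0, atol=1e-10):
                raise ValueError(f"transition {name} rows must sum to 1")
        for name, v in self.variances.items():
            if (v < VAR_FLOOR - 1e-12).any():
                raise ValueError(f"variances of leaf {name} below floor")

    def permuted(self, perm: np.ndarray) -> "MultiTaskModel":
        """Relabel clusters by a permutation (label-symmetry helper)."""
        p = np.asarray(perm)
        return MultiTaskModel(
            tree=self.tree, k=self.k,
            pi=self.pi[p],
            transitions={n: t[np.ix_(p, p)] for n, t in self.transitions.items()},
            means={n: m[p] for n, m in self.means.items()},
            variances={n: v[p] for n, v in self.variances.items()},
        )


@dataclass
class MultiTaskFit:
    model: MultiTaskModel
    assignments: dict[str, ClusterAssignment]
    posteriors: dict[str, np.ndarray]
    loglik_trace: np.ndarray
    converged: bool
    seed: int


def _log_gaussian(x: np.ndarray, means: np.ndarray,
                  variances: np.ndarray) -> np.ndarray:
    """(n, k) log density of rows x under k diagonal Gaussians."""
    n, d = x.shape
    out = np.empty((n, means.shape[0]))
    for c in range(means.shape[0]):
        z = (x - means[c]) ** 2 / variances[c]
        out[:, c] = -0.5 * (z.sum(axis=1)
                            + np.log(variances[c]).sum() + d * LOG_2PI)
    return out


def _message_pass(model: MultiTaskModel, obs: dict[str, np.ndarray]):
    """Exact sum-product over the task tree, vectorized over tuples.

    Returns per-tuple log-likelihoods, per-node posteriors gamma and
    per-branch pair posteriors xi (summed over tuples, in linear space,
    for the M-step).
    """
    tree = model.tree
    nodes = tree.nodes()
    parent = tree.parent_map()
    n = next(iter(obs.values())).shape[0]
    k = model.k
    log_t = {name: np.log(np.clip(t, 1e-300, None))
             for name, t in model.transitions.items()}

    up: dict[int, np.ndarray] = {}
    msg_to_parent: dict[int, np.ndarray] = {}
    for v in reversed(nodes):  # children before parents
        if v.is_leaf:
            beta = _log_gaussian(obs[v.name], model.means[v.name],
                                 model.variances[v.name])
        else:
            beta = np.zeros((n, k))
            for c in v.children:
                beta += msg_to_parent[id(c)]
        up[id(v)] = beta
        if id(v) in parent:
            lt = log_t[v.name]
            # msg[s_p] = logsumexp_{s_c} log T[s_p, s_c] + beta[s_c]
            msg_to_parent[id(v)] = logsumexp(
                lt[None, :, :] + beta[:, None, :], axis=2)

    log_pi = np.log(np.clip(model.pi, 1e-300, None))
    ll_tuples = logsumexp(log_pi[None, :] + up[id(tree.root)], axis=1)

    down: dict[int, np.ndarray] = {id(tree.root): np.broadcast_to(
        log_pi, (n, k))}
    gamma: dict[str, np.ndarray] = {}
    xi_sum: dict[str, np.ndarray] = {}
    for v in nodes:  # parents before children
        g = down[id(v)] + up[id(v)] - ll_tuples[:, None]
        gamma[v.name] = np.exp(g)
        for c in v.children:
            lt = log_t[c.name]
            out_p = down[id(v)] + up[id(v)] - msg_to_parent[id(c)]
            down[id(c)] = logsumexp(
                out_p[:, :, None] + lt[None, :, :], axis=1)
            log_xi = (out_p[:, :, None] + lt[None, :, :]
                      + up[id(c)][:, None, :] - ll_tuples[:, None, None])
            xi_sum[c.name] = np.exp(logsumexp(log_xi, axis=0))
    return ll_tuples, gamma, xi_sum


def tree_loglikelihood(model: MultiTaskModel,
                       obs: dict[str, np.ndarray]) -> float:
    """Exact observed-data log-likelihood of the tuples under the model."""
    ll, _, _ = _message_pass(model, obs)
    return float(ll.sum())


def _hungarian_align(ref: np.ndarray, other: np.ndarray, k: int) -> np.ndarray:
    """Permutation relabeling ``other`` to maximise overlap with ``ref``."""
    from scipy.optimize import linear_sum_assignment
    ct = np.zeros((k, k))
    np.add.at(ct, (ref, other), 1)
    _, col = linear_sum_assignment(-ct.T)
    # row i of ct.T is other-label, assigned to ref-label col[i]
    return col


def _initialize(obs: dict[str, np.ndarray], tree: TaskTree, k: int,
                seed: int, diag_mass: float = 0.8) -> MultiTaskModel:
    """Independent k-means per leaf, IDs aligned to the first leaf by
    Hungarian matching on tuple overlap, Gaussians from those groups."""
    from sklearn.cluster import KMeans
    leaves = tree.leaf_names()
    labels = {}
    for i, leaf in enumerate(leaves):
        km = KMeans(n_clusters=k, n_init=5, random_state=seed + i)
        labels[leaf] = km.fit_predict(obs[leaf])
    ref = labels[leaves[0]]
    for leaf in leaves[1:]:
        perm = _hungarian_align(ref, labels[leaf], k)
        labels[leaf] = perm[labels[leaf]]
    means, variances = {}, {}
    for leaf in leaves:
        x = obs[leaf]
        d = x.shape[1]
        mu = np.zeros((k, d))
        var = np.ones((k, d))
        for c in range(k):
            sel = labels[leaf] == c
            if sel.sum() >= 2:
                mu[c] = x[sel].mean(axis=0)
                var[c] = np.maximum(x[sel].var(axis=0), VAR_FLOOR)
            else:
                mu[c] = x.mean(axis=0)
                var[c] = np.maximum(x.var(axis=0), VAR_FLOOR)
        means[leaf] = mu
        variances[leaf] = var
    trans = {}
    t0 = np.full((k, k), (1.0 - diag_mass) / (k - 1))
    np.fill_diagonal(t0, diag_mass)
    for v in tree.nodes():
        if id(v) in tree.parent_map():
            trans[v.name] = t0.copy()
    return MultiTaskModel(tree=tree, k=k, pi=np.full(k, 1.0 / k),
                          transitions=trans, means=means,
                          variances=variances)


def fit(obs: dict[str, np.ndarray], tree: TaskTree, k: int, seed: int = 0,
        max_iter: int = 500, tol: float = 1e-6,
        init_model: MultiTaskModel | None = None) -> MultiTaskFit:
    """Fit the tree mixture by EM.

    ``obs`` maps each leaf name to its (n_tuples, d) observation matrix
    (spectral-embedding rows restricted to orthologous tuples).  The
    log-likelihood trace is monotone non-decreasing; convergence when the
    relative change drops below ``tol``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    leaves = tree.leaf_names()
    missing = set(leaves) - set(obs)
    if missing:
        raise ValueError(f"observations missing for leaves {sorted(missing)}")
    sizes = {leaf: obs[leaf].shape[0] for leaf in leaves}
    if len(set(sizes.values())) != 1:
        raise ValueError("all leaves must observe the same tuples")
    n = sizes[leaves[0]]
    model = init_model if init_model is not None else _initialize(
        obs, tree, k, seed)
    trace = []
    converged = False
    gamma = None
    for _ in range(max_iter):
        ll_tuples, gamma, xi_sum = _message_pass(model, obs)
        ll = float(ll_tuples.sum())
        trace.append(ll)
        if len(trace) >= 2:
            prev = trace[-2]
            if abs(ll - prev) < tol * (abs(prev) + 1e-12):
                converged = True
                break
        # M-step
        pi = gamma[tree.root.name].sum(axis=0)
        pi = pi / pi.sum()
        transitions = {}
        parent = tree.parent_map()
        for v in tree.nodes():
            if id(v) not in parent:
                continue
            xs = xi_sum[v.name]
            denom = xs.sum(axis=1, keepdims=True)
            transitions[v.name] = np.where(denom > 0, xs / np.maximum(
                denom, 1e-300), 1.0 / k)
        means, variances = {}, {}
        for leaf in leaves:
            g = gamma[leaf]
            x = obs[leaf]
            w = g.sum(axis=0)
            empty = w < 1e-8
            if empty.any():
                logger.warning("empty cluster at leaf %s; re-seeded from "
                               "worst-fit observations", leaf)
            mu = (g.T @ x) / np.maximum(w, 1e-300)[:, None]
            var = (g.T @ (x ** 2)) / np.maximum(w, 1e-300)[:, None] - mu ** 2
            if empty.any():
                fitvals = (g * _log_gaussian(
                    x, model.means[leaf], model.variances[leaf])).sum(axis=1)
                worst = np.argsort(fitvals)
                for j, c in enumerate(np.flatnonzero(empty)):
                    mu[c] = x[worst[j]]
                    var[c] = x.var(axis=0)
            var = np.maximum(var, VAR_FLOOR)
            means[leaf] = mu
            variances[leaf] = var
        model = MultiTaskModel(tree=tree, k=k, pi=pi,
                               transitions=transitions, means=means,
                               variances=variances)
    if not converged:
        # refresh posteriors and trace so they describe the final model
        ll_tuples, gamma, _ = _message_pass(model, obs)
        trace.append(float(ll_tuples.sum()))
    assignments = {}
    posteriors = {}
    for leaf in leaves:
        post = gamma[leaf]
        posteriors[leaf] = post
        assignments[leaf] = ClusterAssignment(post.argmax(axis=1), k=k,
                                              method="multitask", seed=seed)
    return MultiTaskFit(model=model, assignments=assignments,
                        posteriors=posteriors,
                        loglik_trace=np.array(trace), converged=converged,
                        seed=seed)


def posterior_decode(f: MultiTaskFit) -> dict[str, ClusterAssignment]:
    """Posterior-mode labels per leaf (ties break to the lowest index,
    the behaviour of argmax); cluster IDs are shared across leaves by
    construction of the tree model."""
    return {leaf: ClusterAssignment(post.argmax(axis=1), k=f.model.k,
                                    method="multitask")
            for leaf, post in f.posteriors.items()}


def select_tree(candidates: list[TaskTree], obs: dict[str, np.ndarray],
                k: int, seeds=(0, 1, 2), max_iter: int = 500,
                tol: float = 1e-6):
    """Fit every candidate tree with the same seed set and pick the one
    with the best best-of-seeds likelihood (first index wins ties)."""
    if not candidates:
        raise ValueError("need at least one candidate tree")
    results = []
    for tree in candidates:
        best = None
        for s in seeds:
            f = fit(obs, tree, k, seed=s, max_iter=max_iter, tol=tol)
            ll = f.loglik_trace[-1]
            if best is None or ll > best[0]:
                best = (ll, f)
        results.append(best)
    lls = [r[0] for r in results]
    best_idx = int(np.argmax(lls))
    return candidates[best_idx], results[best_idx][1], np.array(lls)
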