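"""End-to-end pipelines: the 15-method benchmark and the multi-task run.

``run_benchmark`` clusters one normalized contact matrix with every
registered method variant, scores each clustering with the five
evaluation criteria, and averages per-criterion ranks.  ``run_multitask``
runs the full multi-dataset pipeline: spectral embedding per leaf, tuple
construction over an orthology map, tree-mixture EM, posterior decoding,
pairwise overlap/conservation statistics and conserved-core extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import cluster as cl
from . import comparative, evaluate, graph, multitask
from .bins_io import ContactMatrix, SignalTrack

logger = logging.getLogger(__name__)

HIGHER_BETTER = {
    "dbi": False,
    "silhouette": True,
    "delta_contact": True,
    "n_enriched": True,
    "anova": True,
}


def _method_registry(k: int, seed: int, restarts: int):
    """The 15 variants: {hierarchical, k-means, spectral} x 5 metrics."""

    def hier(metric):
        return lambda m: cl.hierarchical_cluster(
            cl.distance_matrix(m, metric), k)

    def spectral_fn(metric):
        return lambda m: cl.spectral_cluster(
            graph.embed(m, metric, k), k, seed=seed, restarts=restarts)

    methods = {}
    for metric in ("euclidean", "one_minus_pearson", "one_minus_spearman",
                   "count", "logcount"):
        methods[f"hier_{metric}"] = hier(metric)
    methods["kmeans_euclidean"] = lambda m: cl.kmeans_vector(
        m, "euclidean", k, seed=seed, restarts=restarts)
    methods["kmeans_pearson"] = lambda m: cl.kmeans_vector(
        m, "pearson", k, seed=seed, restarts=restarts)
    methods["kmeans_spearman"] = lambda m: cl.kmeans_spearman(
        m, k, seed=seed, restarts=restarts)
    methods["kmeans_count"] = lambda m: cl.kmeans_counts(
        m, k, log=False, seed=seed, restarts=restarts)
    methods["kmeans_logcount"] = lambda m: cl.kmeans_counts(
        m, k, log=True, seed=seed, restarts=restarts)
    for metric in ("euclidean", "pearson", "spearman", "count", "logcount"):
        methods[f"spectral_{metric}"] = spectral_fn(metric)
    return methods


@dataclass
class BenchmarkResult:
    scores: pd.DataFrame
    average_ranks: pd.Series
    assignments: dict[str, cl.ClusterAssignment]
    failures: dict[str, str] = field(default_factory=dict)


def run_benchmark(m: ContactMatrix, signals: Sequence[SignalTrack],
                  k: int = 10, seed: int = 0, restarts: int = 5,
                  methods: Sequence[str] | None = None,
                  alpha: float = 0.05) -> BenchmarkResult:
    """Cluster with every method variant and rank by the five criteria."""
    registry = _method_registry(k, seed, restarts)
    if methods is not None:
        registry = {name: registry[name] for name in methods}
    if len(registry) < 2:
        raise ValueError("need at least 2 methods to rank")
    d_eval = cl.distance_matrix(m, "one_minus_spearman")
    logC = m.log2p1()
    rows = {}
    assignments = {}
    failures = {}
    for name, fn in registry.items():
        try:
            a = fn(m)
            scores_row = {
                "dbi": evaluate.dbi(d_eval, a),
                "silhouette": evaluate.silhouette(d_eval, a),
                "delta_contact": evaluate.delta_contact(logC, a),
                "n_enriched": evaluate.count_enriched_clusters(
                    signals, a, alpha=alpha),
                "anova": evaluate.anova_score(signals, a),
            }
        except Exception as exc:  # noqa: BLE001 - record and keep ranking
            logger.warning("method %s failed (%s); excluded from ranking",
                           name, exc)
            failures[name] = str(exc)
            continue
        assignments[name] = a
        rows[name] = scores_row
    scores = pd.DataFrame.from_dict(rows, orient="index")
    ranks = evaluate.rank_methods(scores, HIGHER_BETTER)
    return BenchmarkResult(scores=scores, average_ranks=ranks.sort_values(),
                           assignments=assignments, failures=failures)


@dataclass
class MultiTaskResult:
    fit: multitask.MultiTaskFit
    assignments: dict[str, cl.ClusterAssignment]
    overlap: dict[tuple[str, str], comparative.OverlapMatrix]
    conservation: dict[tuple[str, str], float]
    core_lists: dict[int, np.ndarray]
    core_fractions: dict[str, np.ndarray]


def run_multitask(matrices: dict[str, ContactMatrix],
                  tree: multitask.TaskTree, orthology_map,
                  species_of_leaf: dict[str, str], h_species: str,
                  m_species: str, k: int = 10, metric: str = "spearman",
                  seed: int = 0) -> MultiTaskResult:
    """Full multi-dataset pipeline on normalized matrices."""
    if len(orthology_map) == 0:
        raise ValueError("orthology map is empty; nothing to cluster")
    embeddings = {}
    for leaf, m in matrices.items():
        e = graph.embed(m, metric, k)
        if len(e.kept) != m.n:
            raise ValueError(
                f"leaf {leaf}: isolated bins in graph; filter them first")
        embeddings[leaf] = e.X
    tuples = multitask.build_region_tuples(orthology_map, species_of_leaf,
                                           h_species, m_species)
    obs = multitask.tuple_observations(tuples, embeddings)
    f = multitask.fit(obs, tree, k, seed=seed)
    assignments = multitask.posterior_decode(f)
    leaves = tree.leaf_names()
    overlap = {}
    conservation = {}
    for i, la in enumerate(leaves):
        for lb in leaves[i + 1:]:
            om = comparative.overlap_matrix(assignments[la], assignments[lb])
            overlap[(la, lb)] = om
            conservation[(la, lb)] = comparative.conservation_score(om)
    core_lists, core_fractions = comparative.conserved_core(assignments,
                                                            tuples, k)
    return MultiTaskResult(fit=f, assignments=assignments, overlap=overlap,
                           conservation=conservation, core_lists=core_lists,
                           core_fractions=core_fractions)
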