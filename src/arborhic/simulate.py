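"""Synthetic-data generators with full ground truth.

These generators emulate the inputs the rest of the package consumes,
so every pipeline can be exercised and validated without external data:

* planted-cluster contact matrices — Poisson counts with higher mean
  within planted clusters than across, optionally modulated by a
  power-law distance decay on intra-chromosomal pairs;
* label evolution along a task tree — root labels from a prior, children
  resampled through per-branch transition matrices (the generative twin
  of the multi-task model);
* multi-dataset bundles — per-leaf matrices conditioned on evolved
  labels, plus a planted orthology bijection;
* cluster-enriched Poisson signal tracks;
* synthetic UCSC chain files realising a planted bin bijection.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bins_io import BIN_COLUMNS, BinTable, ContactMatrix, SignalTrack
from .multitask import TaskTree

DEFAULT_BIN_SIZE = 1_000_000


@dataclass
class SimulationConfig:
    """Conditions for one planted-cluster contact matrix.

    lambda_in / lambda_out are the Poisson means for within- and
    cross-cluster contacts; ``chrom_sizes`` gives bins per chromosome
    (summing to n_regions); ``decay_alpha`` optionally applies a
    (1+|i-j|)^-alpha factor to intra-chromosomal means.
    """

    n_regions: int = 200
    k: int = 4
    lambda_in: float = 20.0
    lambda_out: float = 2.0
    chrom_sizes: dict[str, int] = field(default_factory=dict)
    decay_alpha: float | None = None
    bin_size: int = DEFAULT_BIN_SIZE
    seed: int = 0

    def __post_init__(self):
        if not self.chrom_sizes:
            self.chrom_sizes = {"chr1": self.n_regions}
        if sum(self.chrom_sizes.values()) != self.n_regions:
            raise ValueError("chromosome sizes must sum to n_regions")
        if not self.lambda_in > self.lambda_out >= 0:
            raise ValueError("need lambda_in > lambda_out >= 0")


@dataclass
class GroundTruth:
    labels: dict[str, np.ndarray] = field(default_factory=dict)
    tree: TaskTree | None = None
    transitions: dict[str, np.ndarray] = field(default_factory=dict)
    orthology: list[tuple[int, int]] = field(default_factory=list)
    enriched_clusters: dict[str, set] = field(default_factory=dict)


def _bins_for(cfg: SimulationConfig) -> BinTable:
    rows = []
    idx = 0
    for chrom, nbins in cfg.chrom_sizes.items():
        for b in range(nbins):
            rows.append((chrom, b * cfg.bin_size, (b + 1) * cfg.bin_size,
                         idx))
            idx += 1
    return BinTable(pd.DataFrame(rows, columns=BIN_COLUMNS))


def simulate_contact_matrix(cfg: SimulationConfig,
                            labels: np.ndarray | None = None,
                            rng: np.random.Generator | None = None,
                            ) -> tuple[ContactMatrix, GroundTruth]:
    """Planted-cluster Poisson contact matrix.

    Entry (i, j) ~ Poisson(lambda_in) when i and j share a planted label,
    Poisson(lambda_out) otherwise; with ``decay_alpha`` set, the mean of
    intra-chromosomal pairs is additionally multiplied by
    (1 + |i-j|)^-alpha.  ``labels`` may be supplied (e.g. tree-evolved);
    otherwise balanced labels are drawn from the seed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_regions
    if labels is None:
        labels = rng.permutation(np.arange(n) % cfg.k)
    labels = np.asarray(labels, dtype=int)
    same = labels[:, None] == labels[None, :]
    mean = np.where(same, cfg.lambda_in, cfg.lambda_out).astype(float)
    bins = _bins_for(cfg)
    if cfg.decay_alpha is not None:
        chroms = bins.chroms
        idx = np.arange(n)
        cis = chroms[:, None] == chroms[None, :]
        decay = (1.0 + np.abs(idx[:, None] - idx[None, :])) ** -cfg.decay_alpha
        mean = np.where(cis, mean * decay, mean)
    upper = rng.poisson(np.triu(mean))
    counts = np.triu(upper) + np.triu(upper, k=1).T
    truth = GroundTruth(labels={"single": labels})
    return ContactMatrix(bins, counts.astype(float)), truth


def simulate_tree_labels(tree: TaskTree, k: int, pi: np.ndarray,
                         transitions: dict[str, np.ndarray], n: int,
                         seed: int = 0) -> dict[str, np.ndarray]:
    """Evolve per-region labels down the task tree.

    Root labels ~ pi; each child's label is drawn from the row of its
    branch transition matrix indexed by the parent label.  Returns labels
    for every node (internal and leaf) keyed by node name.
    """
    rng = np.random.default_rng(seed)
    pi = np.asarray(pi, dtype=float)
    if not np.isclose(pi.sum(), 1.0):
        raise ValueError("pi must be a probability vector")
    for name, t in transitions.items():
        if not np.allclose(np.asarray(t).sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"transition rows for branch {name} must sum to 1")
    out = {}
    root_labels = rng.choice(k, size=n, p=pi)
    out[tree.root.name] = root_labels

    def walk(node):
        for child in node.children:
            t = np.asarray(transitions[child.name], dtype=float)
            parent_labels = out[node.name]
            u = rng.random(n)
            cum = np.cumsum(t, axis=1)
            child_labels = (u[:, None] > cum[parent_labels]).sum(axis=1)
            out[child.name] = child_labels
            walk(child)

    walk(tree.root)
    return out


def make_transitions(tree: TaskTree, k: int,
                     diag_mass: float | dict[str, float]) -> dict[str, np.ndarray]:
    """Per-branch transition matrices with the given diagonal mass and the
    remainder spread uniformly off-diagonal."""
    out = {}
    parent = tree.parent_map()
    for v in tree.nodes():
        if id(v) not in parent:
            continue
        dm = diag_mass[v.name] if isinstance(diag_mass, dict) else diag_mass
        t = np.full((k, k), (1.0 - dm) / (k - 1))
        np.fill_diagonal(t, dm)
        out[v.name] = t
    return out


def simulate_multitask_dataset(tree: TaskTree, cfg: SimulationConfig,
                               transitions: dict[str, np.ndarray],
                               seed: int = 0, m_leaves=(),
                               ) -> tuple[dict[str, ContactMatrix],
                                          list[tuple[int, int]], GroundTruth]:
    """Per-leaf contact matrices with tree-evolved planted labels and a
    planted orthology bijection (a seeded shuffle of bin indices).

    Leaves named in ``m_leaves`` play the second genome: region r lives at
    bin index ``shuffled[r]`` there, and the returned orthology pairs
    (r, shuffled[r]) link the two bin spaces.  GroundTruth labels stay in
    region (tuple) order for every leaf.
    """
    rng = np.random.default_rng(seed)
    k = cfg.k
    n = cfg.n_regions
    pi = np.full(k, 1.0 / k)
    node_labels = simulate_tree_labels(tree, k, pi, transitions, n,
                                       seed=int(rng.integers(2 ** 31)))
    shuffled = rng.permutation(n)
    matrices = {}
    for leaf in tree.leaf_names():
        region_labels = node_labels[leaf]
        if leaf in m_leaves:
            bin_labels = np.empty(n, dtype=int)
            bin_labels[shuffled] = region_labels
        else:
            bin_labels = region_labels
        sub_rng = np.random.default_rng(int(rng.integers(2 ** 31)))
        m, _ = simulate_contact_matrix(cfg, labels=bin_labels, rng=sub_rng)
        matrices[leaf] = m
    orthology = sorted((int(h), int(shuffled[h])) for h in range(n))
    truth = GroundTruth(labels=node_labels, tree=tree,
                        transitions=transitions, orthology=orthology)
    return matrices, orthology, truth


def simulate_gaussian_observations(labels: dict[str, np.ndarray], k: int,
                                   d: int, separation: float = 3.0,
                                   noise: float = 1.0, seed: int = 0,
                                   ) -> dict[str, np.ndarray]:
    """Directly emit per-leaf Gaussian observations from given labels.

    Cluster means are placed at ``separation`` times random unit
    directions (shared across leaves), observations get isotropic noise;
    this mirrors what a spectral embedding of a strongly clustered map
    looks like and gives an exact generative twin of the emission model.
    """
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=(max(k, d), d))
    if k <= d:
        # orthonormal directions: every center pair is separation*sqrt(2)
        # apart, so the regime's difficulty does not depend on the draw
        q, _ = np.linalg.qr(raw.T)
        centers = separation * q.T[:k]
    else:
        centers = separation * raw[:k] / np.linalg.norm(raw[:k], axis=1,
                                                        keepdims=True)
    out = {}
    for leaf, lab in labels.items():
        out[leaf] = centers[lab] + noise * rng.normal(size=(len(lab), d))
    return out


def simulate_signal(labels: np.ndarray, enriched_clusters, bins: BinTable,
                    base_rate: float = 20.0, effect: float = 3.0,
                    seed: int = 0, name: str = "sim") -> SignalTrack:
    """Poisson per-bin counts with rate base_rate*(1+effect) inside the
    enriched clusters and base_rate elsewhere."""
    if effect < 0:
        raise ValueError("effect must be >= 0")
    rng = np.random.default_rng(seed)
    enriched = np.isin(labels, list(enriched_clusters))
    rate = base_rate * (1.0 + effect * enriched)
    values = rng.poisson(rate).astype(float)
    return SignalTrack(bins, values, kind="peak_count", name=name)


def simulate_chain(bijection, bins_h: BinTable, bins_m: BinTable,
                   aligned_fraction: float = 0.2, seed: int = 0) -> str:
    """Emit UCSC chain text realising a planted bin bijection.

    For each (h_bin, m_bin) pair, one chain with two ungapped blocks whose
    total length is aligned_fraction * bin length is placed inside the two
    bins.  The result parses with the chain reader and, fed through
    aggregation, reciprocal-best selection and the aligned-fraction
    filter, recovers the bijection.
    """
    if not 0 < aligned_fraction <= 1:
        raise ValueError("aligned_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    chrom_sizes_h = bins_h.frame.groupby("chrom")["end"].max().to_dict()
    chrom_sizes_m = bins_m.frame.groupby("chrom")["end"].max().to_dict()
    lines = []
    for cid, (h, m) in enumerate(sorted(bijection), start=1):
        hrow = bins_h.frame.iloc[h]
        mrow = bins_m.frame.iloc[m]
        length = int(aligned_fraction * (hrow["end"] - hrow["start"]))
        b1 = length // 2
        b2 = length - b1
        gap = int(rng.integers(10, 100))
        t_start = int(hrow["start"])
        q_start = int(mrow["start"])
        t_end = t_start + length + gap
        q_end = q_start + length + gap
        lines.append(
            f"chain 1000 {hrow['chrom']} {chrom_sizes_h[hrow['chrom']]} + "
            f"{t_start} {t_end} {mrow['chrom']} "
            f"{chrom_sizes_m[mrow['chrom']]} + {q_start} {q_end} {cid}"
        )
        lines.append(f"{b1} {gap} {gap}")
        lines.append(f"{b2}")
        lines.append("")
    return "\n".join(lines)
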