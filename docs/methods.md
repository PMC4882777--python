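# Methods

## Coordinates, bins and input formats

All genomic coordinates are 0-based half-open.  The bin table (chrom,
start, end, index) is the single source of region identity; indices are
contiguous `0..n−1` sorted by (chrom, start).  Contact matrices are read
from dense numeric grids or sparse `(i, j, count)` triples; triples are
mirrored on read so the in-memory matrix is always symmetric (tolerance
1e−9).  1D tracks come as BED3+ (peaks, coverage intervals) or 4-column
bedGraph (value tracks).

Per-bin signal summaries follow three conventions:

* **peak counts** — each peak is assigned to the bin containing its
  midpoint.  The midpoint rule is unambiguous and count-conserving: a
  peak straddling a bin boundary is counted once.
* **coverage fraction** — covered bases of the union of intervals divided
  by bin length; overlapping intervals are merged first, so double
  coverage is not double counted, and splitting an interval in two leaves
  the result unchanged.
* **length-weighted mean** — for value tracks (e.g. replication timing);
  bins with no overlapping record carry NaN, and all downstream
  statistics drop missing values pairwise.

## ICE normalization

Iterative correction removes multiplicative per-bin biases: counts are
repeatedly divided by the outer product of row-marginal ratios until the
coefficient of variation of nonzero-row sums falls below `tol` (default
1e−6, `max_iter` 200).  Bins with a zero raw marginal are excluded from
balancing (bias = NaN, rows stay zero) and should be excluded from
clustering.  The diagonal is retained — the downstream graph construction
decides what to do with self-interactions.  Output is scaled so included
row sums equal their mean raw marginal.

## Similarity graphs and spectral embedding

Distances and correlations between bins are computed on
log2(count + 1)-transformed rows; the pseudocount of 1 handles the exact
zeros a binned contact map always contains.  The full row — including the
diagonal entry — enters the correlation/distance, but `A(i,i)` is forced
to 0 for the correlation metrics so self-loops never dominate vertex
degrees.  Spearman correlation uses average ranks for ties.  Negative
correlations are clipped to 0: anti-correlated interaction profiles carry
no edge rather than a negative weight, keeping the Laplacian well
defined.

The normalized Laplacian is `L = D^{-1/2} A D^{-1/2}`; its spectrum lies
in [−1, 1].  Zero-degree vertices are removed before the decomposition
with an index map retained.  Eigenvectors come from a full symmetric
eigendecomposition — deterministic for a fixed input — sorted by
descending eigenvalue, each column's sign fixed so its largest-magnitude
entry is positive.

**Bounding the number of clusters.**  The off-diagonal upper-triangle
weights are shuffled (preserving the weight multiset, not the degree
sequence) to build `n_perm` null graphs.  Scanning from the top of the
spectrum, the suggested bound is the last position in the contiguous run
of observed eigenvalues exceeding the position-wise (1−α) null quantile.
Scanning contiguously matters: each deep spectrum position exceeds its
null quantile with probability ≈ α by chance, so a global "largest
exceeding index" rule would return ≈ n on structureless input instead of
1.  Degree-preserving null models are out of scope.

## Single-dataset clustering (15 variants)

Three algorithm families × five metrics.  Count/log-count distances are
`max(matrix) − matrix` with the diagonal forced to 0; the other three are
computed between log2 rows.

* **Hierarchical**: average linkage cut with `maxclust = k`, then
  rebalancing — while fewer than k clusters of ≥ `min_size` (default 10)
  members exist, the largest cluster is re-split in two by average
  linkage; afterwards clusters below `min_size` are absorbed into the
  largest cluster.  Splitting terminates when the largest cluster cannot
  be split further.
* **k-means (Euclidean / Pearson)**: standard Lloyd iterations (best of
  `restarts`, default 10); the Pearson variant z-scores rows first, which
  makes squared Euclidean distance monotone in 1 − r.
* **k-means (Spearman)**: centroids are arithmetic means of member rows;
  assignment minimizes 1 − Spearman(row, centroid); a sweep that fails to
  decrease the objective is not applied, so the objective trace is
  monotone non-increasing.  A constant centroid gets the worst distance
  (1) and is logged.
* **k-means (counts / log counts)**: graph k-means — each bin is
  reassigned to the cluster maximising its mean (log) contact count to
  that cluster's current members (self pair excluded); empty clusters are
  re-seeded with the globally least-connected bin; non-improving sweeps
  are rolled back, making the objective non-decreasing and leaving a
  degenerate (uniform) matrix at its initialization.
* **Spectral**: Euclidean k-means on the rows of the top-k eigenvector
  matrix.

The exact update order of the count-based k-means is this package's own
definition, stated here rather than inferred from prior art.

## Evaluation criteria

All internal indices default to 1 − Spearman distance; the metric is a
parameter.

* **DBI** `= (1/k) Σ_i max_{j≠i} (d̄_i + d̄_j)/d_{i,j}` with *mean
  pairwise* within-distances (not centroid distances, since not every
  method has centroids).  Lower is better.
* **Silhouette** is the mean over clusters of per-cluster mean `s_j` —
  the cluster-balanced version, not the global element mean.
* **Delta contact count**: mean over clusters of (within − between)
  average log contact; self pairs excluded.
* **Signal enrichment**: one-sided two-sample KS test of "inside the
  cluster stochastically larger than outside", statistic
  `D⁻ = max_x(F_out − F_in)`.  The default p-value is the **exact
  conditional** probability `P(D⁻ ≥ observed)` under uniform relabeling
  of the pooled sample, computed by dynamic programming over partial
  ECDFs with hypergeometric transition kernels.  This is tie-aware —
  essential for count-valued signals, where ties otherwise make any
  continuity-assuming KS p-value conservative — and reduces exactly to
  the classical exact one-sided two-sample KS p-value on continuous data
  (verified against an independent implementation).  The large-sample
  bound `exp(−2mnD²/(m+n))` is available as `method="asymptotic"`; it is
  noticeably conservative below a few hundred points per side.  A cluster
  is enriched at p < 0.05; a clustering's score is the number of clusters
  enriched for ≥ 1 signal.
* **ANOVA score**: Σ over signals of −log10 p of the one-way F test of
  the signal across clusters (p floored at 1e−300; constant signals
  contribute 0).  The log base only rescales the score; ranks are the
  consumed output.
* **Ranking**: per criterion, rank 1 = best with mean ranks for ties;
  methods are compared by their average rank across criteria.  Degenerate
  clusterings (e.g. a rebalancing collapse to one cluster) are recorded
  as failures and excluded from the ranking with a warning.

Degenerate conventions, all logged: singleton cluster scatter d̄ = 0;
silhouette 0/0 → 0; empty KS side → p = 1.

## A/B compartments

From **raw** (pre-ICE) counts: the expected contact count `I_s` at each
bin distance `s` is the genome-wide mean over intra-chromosomal pairs
(pooled across chromosomes, not per chromosome).  Per chromosome, the
observed/expected matrix `M(i,j) = counts(i,j)/I_{|i−j|}` (zero-expected
distances yield 0 with a warning) is column-wise Spearman-correlated and
the first principal component of that correlation matrix is split by
sign.  Orientation: nothing in the matrix itself identifies which sign is
the active compartment, so the larger group is labeled "A" by convention;
callers may re-anchor with an activity track.  Partition agreement is
quantified by the pair-counting F score (precision `o/s` against the
first partition, recall `o/c` against the second; note `2pr/(p+r)` is
symmetric in its two arguments even though p and r individually are not)
and the Rand index `(o + b)/C(n,2)`.

## Orthologous bins

Two evidence sources are reduced to an aligned-base-pair table
`A(h_bin, m_bin)`: UCSC chain files (ungapped blocks split at the bin
boundaries of both genomes, reverse-strand query coordinates converted
per the chain spec) and 12-column blast-style tabular alignments (1-based
inclusive coordinates, e-value filter, default 1e−5).  Reciprocal best
hits — `m = argmax A(h,·)` and `h = argmax A(·,m)` — give a one-to-one
map; ties break to the lower bin index (logged).  The aligned-fraction
filter keeps pairs with `A ≥ frac·r` (bin size r, default frac 0.1,
boundary inclusive).  Maps from the two sources can be intersected for a
stringent final set.

## Multi-task tree mixture

The generative model per orthologous region tuple: root label ~ π; each
child label ~ the parent-indexed row of its branch's k×k transition
matrix; each leaf emits its spectral-embedding row from a
diagonal-covariance Gaussian indexed by the leaf label.  Internal nodes
carry no emissions.  One transition matrix is learned per branch (tied
matrices are the constrained special case).  Embeddings are computed on
each full dataset first, then row-restricted to the orthologous tuples;
only complete tuples are used by default.

Inference is exact sum-product per tuple (upward and downward messages in
log space, log-sum-exp normalization), vectorized over tuples.  EM
alternates this E-step with closed-form M-steps for π, every transition
matrix, and the leaf Gaussians; variances are floored at 1e−6.  The
log-likelihood trace is monotone non-decreasing; convergence is declared
at relative change < 1e−6 (max 500 iterations).  Initialization:
independent k-means per leaf, leaf cluster IDs aligned to the first leaf
by Hungarian matching on tuple overlap, transitions started at diagonal
mass 0.8, π uniform.  Empty clusters at a leaf are re-seeded from the
worst-fit observations.  Decoding takes the posterior mode per leaf; ties
break to the lowest index.  With a single-leaf tree the model collapses
to a diagonal-covariance Gaussian mixture with weights `π @ T`, and the
EM trajectory coincides step-by-step with plain GMM EM — this reduction
is used as a correctness oracle in the tests.

**Tree choice.**  Candidate trees are each fit with the same seed set and
compared by best-of-seeds likelihood (all likelihoods are reported; the
argmax ties to the first candidate).

## Cross-dataset comparison

Cluster-pair overlap over the mapped universe M uses the upper-tail
hypergeometric probability `P(X ≥ o)` with the row-dataset cluster as
successes and the column-dataset cluster as draws (the statistic is
near-symmetric at these sizes); entries are −log10 p, floored at 0 and
capped at 300 to keep heat maps finite.  The conservation score is
Σ diagonal − Σ off-diagonal.  For independently produced clusterings,
cluster IDs are first aligned by Hungarian matching on overlap counts;
among equally optimal matchings the lexicographically smallest
permutation is returned (certified optimal against exhaustive search for
k ≤ 6 in the tests).  Divergence events between activity classes count
off-diagonal cells with −log10 p above a threshold (default 2, i.e.
p ≤ 0.01 — a parameter, as no canonical cutoff exists), binned by the
(high/low) classes of the row and column clusters.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of configuration + seed.

* **Contact matrices**: Poisson counts with mean λ_in within planted
  clusters and λ_out across (defaults 20/2 — a strong-signal regime in
  which spectral recovery is expected to be essentially exact), optional
  multiplicative `(1+|i−j|)^{−α}` intra-chromosomal distance decay.
  Poisson (not negative binomial) is the simplest noise model that
  exercises every consumer; overdispersion is an extension hook.
* **Tree-evolved labels**: root from π, children through per-branch
  transitions — the exact generative twin of the multi-task model.
* **Multi-dataset bundles**: per-leaf matrices conditioned on evolved
  labels; the planted orthology bijection is a seeded shuffle of bin
  indices, and leaves designated as the second genome have their labels
  permuted into that genome's bin space so matrices and map stay
  consistent.
* **Gaussian observations**: for direct emission-level experiments,
  cluster centers sit on random *orthonormal* directions scaled by
  `separation` (default 3.0, noise SD 1.0) when k ≤ d, so every center
  pair is `separation·√2` apart and the difficulty of the regime does not
  depend on the draw.
* **Signals**: Poisson per-bin counts at `base_rate·(1+effect·enriched)`;
  the default base rate of 20 per bin reflects typical transcription
  factor peak counts in 1-Mbp bins.  At much lower rates heavy ties make
  any honest KS test conservative — a property of count data, not of the
  implementation.
* **Chains**: two ungapped blocks per planted pair totalling
  `aligned_fraction·r` bases, in valid chain syntax.

Synthetic matrices are exchangeable within clusters and lack real Hi-C
features — translocation artifacts, copy-number effects, unmappable
regions, resolution-dependent decay curvature.  Passing tests certify
the algorithms' contracts (recovery of planted structure, calibration,
formula correctness), not biological conclusions on real data.

### Chosen study conditions for the replicate-level checks

Problem sizes were chosen so that each check exercises the informative
regime of its method: spectral recovery at n = 200 bins, k = 4, λ = 20/2
(50 seeds); compartments at n = 100, alternating blocks of 10, λ = 60/30
with decay α = 1 (50 seeds); multi-task parameter recovery at n = 2000
tuples, k = 4, 4 leaves, diagonal transition mass 0.85 (20 seeds); tree
selection at n = 800 with within-pair branch diagonal 0.95 vs internal
0.7 and separation 2.0 (20 replicates).  The conservation-margin
comparison runs at λ_in/λ_out = 3/2, n = 200, k = 5: with a strong signal
both the tree-coupled and the independent route recover labels perfectly
and their margins tie exactly, so the advantage of information sharing is
only visible — and is claimed only — in the moderate-noise regime where
clustering is genuinely hard.  The 15-method benchmark comparison is run
at λ_in = 3 for the same reason: with trivial signal all methods tie and
ranks are arbitrary.

## Known limitations

* Dense eigendecompositions and O(n²) graph construction target desk
  scale (≲ 5,000 bins per dataset), not 100-kb whole-genome maps.
* Orthology composition across more than two genomes is the caller's
  job; maps are pairwise.
* Branch transitions are unconstrained row-stochastic matrices; branch
  lengths in Newick input are ignored with a warning.
* The exact KS p-value costs O(values · m · multiplicity) per test;
  for samples beyond a few thousand per side the asymptotic method is
  the practical choice.
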