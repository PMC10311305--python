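# Methods

## Overview

`cellbrf` selects genes for single-cell clustering in five stages:
preprocessing, label prediction, class balancing, forest-based gene
importance, and redundancy-pruned selection. The guiding assumption is
that genes worth keeping are those that discriminate cell populations —
so the method first *predicts* populations without supervision, then
scores genes by how much they contribute to separating them, taking
care that rare populations are not drowned out by abundant ones.

## Preprocessing

Genes expressed (value > 0) in fewer than `min_cells` (default 3) cells
are removed; "expressed" means strictly positive, so the rule is
meaningful for normalized as well as raw input. Cells are normalized by
library-size factors relative to the **median** depth — the common
scRNA-seq convention when no spike-ins are available — and transformed
as X′ = log₂(X/s + 1). Median scaling (rather than mean or a fixed
target sum) makes the factors robust to a few very deep cells and leaves
a uniform-depth dataset untouched. Zero-depth cells have no defined
factor and are removed with a warning before factors are computed.

## Label prediction

Cells are embedded with PCA (top `n_pcs` = 50 components, capped at
min(50, c−1, g); exact SVD solver so results are seed-independent),
connected into a binary k-nearest-neighbor graph (`knn_k` = 15,
Euclidean distances in PC space), and partitioned by spectral clustering
(normalized Laplacian embedding, k-means assignment with 10 seeded
restarts). Design choices where the procedure was genuinely open:

* **Graph weights/symmetrization** — binary edges, union symmetrization
  (an edge exists if either endpoint selects the other). Binary weights
  keep the Laplacian spectrum scale-free; union keeps every cell
  connected to at least k neighbors.
* **Neighbor ties** — ties at the k-th distance break by cell index
  (stable argsort over exact pairwise distances), making the graph
  deterministic and permutation-auditable.
* **Number of clusters** — user-supplied when known. With
  `n_clusters="auto"` the largest eigengap of the normalized Laplacian
  spectrum over candidate counts 2..15 is used; on data with well
  separated populations the spectrum has as many near-zero eigenvalues
  as populations, and the gap after them is large.
* Labels are relabeled so cluster 0 is the largest (ties toward the
  lower original label), which makes outputs comparable across runs.

## Class balancing

With c cells in n predicted clusters, the reference size is h = c/n and
the **central cluster** is the one whose size is closest to h (ties go
to the smaller cluster, then the lower id). Clusters smaller than the
central one (*rare*) are oversampled; larger ones (*major*) are
undersampled. Balancing operates in the log-normalized gene space — the
same space the forest trains in.

* **Oversampling** — each rare cluster is grown to exactly the central
  size, i.e. T_central − T_rare synthetic cells. The t-th synthetic cell
  takes seed cell i = t mod T_rare (cycling in column order), draws j
  uniformly from i's `smote_k` = 5 nearest within-cluster neighbors
  (k clipped to cluster size − 1) and emits i + u·(j − i) with
  u ~ Uniform(0,1). The convex form guarantees synthetics stay
  componentwise inside the segment between their two parents; a
  single-cell cluster cannot be interpolated and is duplicated with a
  warning. smote_k = 5 is the canonical SMOTE default.
* **Undersampling** — each major cluster keeps the
  max(1, ⌊U·T⌋) cells closest to its centroid (`retain_fraction_U` =
  0.8, distance ties by index). Keeping the core of the cluster
  sacrifices boundary cells, which are the ones most likely to carry
  label noise.
* `balance_mode` ∈ {both, over_only, under_only, none} switches either
  half off, supporting ablation of the balancing strategy.

Balancing provably never increases the Balance Entropy of the label
distribution, and with a fixed seed is bit-reproducible.

## Gene importance

A forest of `n_trees` = 100 CART classifiers is fit on **all** balanced
cells — no bootstrap resampling, so every tree is trained against the
same labels — with randomness entering through split-candidate
sampling: at every node, ⌈√g⌉ random genes (config `subspace`: "sqrt",
"all", or an integer) are candidates for the best Gini split. Per-split
sampling rather than a single per-tree gene subspace is a deliberate
choice: with one subspace of √g per tree, a gene is visible to the
forest in only n_trees·√g/g trees (≈ 2 of 100 at g = 2000), so a
meaningful fraction of genuinely informative genes would receive zero
importance by lottery; per-split sampling keeps every gene visible to
every tree while still decorrelating them. Trees grow to purity
(min-leaf 1, no depth cap), with thresholds at midpoints of sorted
distinct values — standard CART.

Importance is mean decrease in impurity, computed explicitly from node
tables exported off the fitted trees (per-node class counts are
recomputed from decision paths, so they are exact integers):

* node Gini impurity I = 1 − Σ_C p_C²,
* node importance N = w·I − w_l·I_l − w_r·I_r with absolute cell
  counts w,
* per-tree gene importance f_i = Σ_{a∈M_i} N_a / Σ_{b∈M} N_b over
  internal nodes, which sums to 1 whenever any split reduces impurity,
* forest importance = mean of per-tree vectors, with summary statistics
  μ (mean) and σ (population standard deviation).

Tree induction itself is delegated to scikit-learn's
`DecisionTreeClassifier`; the impurity equations above are this
package's own code and are cross-checked in the tests against an
independent plain-loop traversal of the exported node tables.

## Selection

Genes with f ≥ μ + 3σ form the candidate list, ordered by importance
descending (ties by gene index). If nothing clears the cut — possible
when importance is spread thin — the single top gene is returned with a
warning. The list is then pruned: scanning anchors in order over
surviving genes, any later survivor whose Pearson correlation with the
anchor exceeds h′ = v + v′/(L+1) is removed (v = 0.8, v′ = 0.1). L is
the number of surviving genes after the current anchor, evaluated once
per anchor before its scan; the threshold is therefore strictest for
the top-ranked anchors and relaxes toward v down the list. Choices
where the rule was underdetermined:

* **Signed correlation** — the comparison is S > h′ with S the signed
  Pearson correlation; anti-correlated genes carry complementary
  information and are never removed.
* **Correlation space** — correlations are computed on the
  log-normalized matrix over all cells (not the balanced training set):
  redundancy is a property of the data being described, not of the
  resampled training set.
* **Zero-variance genes** — correlation defined as 0 (warned), so a
  constant gene is never removed *as redundant* (it will in practice
  never pass the importance cut).

The audit trail records, for every removed gene, which anchor removed
it, the correlation and the threshold in force.

## Evaluation statistics

* **k-NN consistency** F′_k = Σ_i Σ_{j∈kNN(i)} F(i,j)/(ck): the mean
  fraction of each cell's k nearest Euclidean neighbors (self excluded,
  distance ties by index) sharing its type. Self-exclusion avoids a
  uniform +1/k inflation.
* **Shannon entropy / Balance Entropy** H = −Σ (T_i/c) ln(T_i/c), BE =
  1 − H/ln n. BE is invariant to the logarithm base; H is reported in
  nats. BE = 0 for balanced classes; BE is defined as 0 for n = 1.
* ARI, NMI and silhouette are standard measures delegated to
  scikit-learn.

## Synthetic data generator

The generator emulates exactly the structure the pipeline is sensitive
to: per-cluster negative-binomial counts (mean m, size r ⇒ variance
m + m²/r), a designated set of informative genes whose mean is shifted
2^LFC-fold in one assigned cluster (assignment round-robin so every
cluster, including rare ones, carries markers), cluster sizes from
largest-remainder rounding of the requested proportions, optional
exact-duplicate genes, and a seeded shuffle of cell order. Defaults:
base mean 5 counts, LFC 2 (4-fold), NB size r = 10 — a biological
coefficient of variation of ≈ 0.32, a moderate overdispersion level by
the conventions of scRNA-seq count simulators.

What it deliberately does **not** emulate: per-gene mean/dispersion
heterogeneity, dropout beyond NB zeros, batch effects, trajectory
(continuous) structure, or correlated marker programs. Passing tests on
this generator therefore demonstrate the pipeline's correctness and its
behavior under imbalance and redundancy — not robustness to the full
messiness of real data, where label-prediction quality is the dominant
limiting factor.

## Numerical and reproducibility notes

* All randomness flows from a single integer seed per run; sub-seeds
  for balancing and each tree are drawn from a `default_rng(seed)`
  stream, and two runs with the same config and seed are byte-identical
  down to the written gene lists.
* Exact pairwise distances with stable argsort (not approximate
  neighbor search) are used everywhere neighbor order matters, chunked
  to bound memory at large c.
* Problem sizes used in the shipped test-and-acceptance workloads
  (≤ 1000 cells × 2000 genes, 10 seeds) were chosen so the full suite
  runs in a few minutes on one CPU while still containing a 5% rare
  population and a 20:3:2 imbalance.

## Known limitations

* The quality of the selected genes is bounded by the quality of the
  predicted labels; badly merged clusters leave their markers unscored.
  The label-controlled ablation in the acceptance workload exists
  precisely to separate this effect from the balancing machinery.
* The three-sigma rule presumes importance is concentrated in a small
  minority of genes; when more than ~5–10% of genes are informative, σ
  is inflated by the signal itself and the cut keeps only the strongest
  markers.
* Oversampling interpolates linearly in log space, which cannot create
  variation outside the convex hull of a rare cluster.
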