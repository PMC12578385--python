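# Methods

## Differential expression

For each (cell type, contrast) the two groups' cells are selected on one
expression layer and, per gene, three statistics are computed:

1. **Earth mover's distance.** The first-order 1-D Wasserstein distance
   between the two empirical distributions, computed as the area between the
   empirical CDFs over the pooled support. For equal group sizes this reduces
   to the mean absolute difference of the sorted samples (the sorted-pairing
   theorem), which is the fast path the vectorized implementation takes; the
   general unequal-size path accumulates `|F_x − F_y| · Δv` over pooled sorted
   values. The EMD is given a sign by `sign(mean(alt) − mean(ref))`; a pure
   spread change with exactly equal means has sign 0 and direction `none`.
   The sign convention is a package decision — the statistic itself is
   unsigned, but up/down DEG counts require a direction, and the mean
   difference is consistent with the fold change's direction.
2. **Mann–Whitney U.** Two-sided, midranks for ties, tie-corrected variance,
   0.5 continuity correction, normal approximation — the only tractable choice
   at thousands of genes × hundreds of cells. The scalar `mwu_test` defaults
   to the exact null distribution for small tie-free samples (scipy's standard
   policy), where the normal approximation is visibly biased. A pooled sample
   with zero range is degenerate: U = n₁n₂/2, p = 1. p-values are
   Benjamini–Hochberg adjusted across the genes of one (cell type, contrast) —
   each comparison is its own BH family.
3. **log2 fold change** of group means with pseudocount 0.01 on both means
   (configurable); the pseudocount keeps zero-mean genes finite.

The joint DEG gate is `p_adj < 0.01 and |EMD| ≥ 0.1` (both thresholds
configurable). The magnitude gate is what keeps trivially small shifts — which
become statistically detectable at large n — out of the DEG lists; the
p-value gate is what controls false positives, since at a few hundred cells
the null EMD of a moderately expressed gene can reach ~0.1–0.3 by sampling
noise alone. Neither gate alone is calibrated; jointly the null DEG rate is
≈ 0 in the validation studies.

Cell types where either group has fewer than `min_cells_per_group` (default
20) cells are skipped with a logged warning, never silently dropped. Optional
subsampling equalizes every group of a cell type to the smallest group
(uniform, without replacement, seeded) before testing, to make DEG counts
comparable across groups of unequal nuclei yield.

EMD units: the statistic is on the scale of the chosen layer (square root of
library-size-normalized counts by default), so the 0.1 gate means "0.1
sqrt-counts of transport".

## QC and normalization

The QC pass is single and order-fixed: genes detected (count > 0) in fewer
than 3 cells are removed first; then, on the gene-filtered matrix, cells
detecting fewer than 500 genes and cells with a mitochondrial count share
strictly greater than 5 % are removed. "Detected" means count > 0; the
mitochondrial share comparison is strict at equality (a configuration flag
makes it inclusive). Mitochondrial genes are recognized by the
case-insensitive `mt-` name prefix (mouse convention), with an explicit flag
vector as override. Because the gene filter is evaluated once, re-running QC
on its own output is a no-op in ordinary regimes; in pathological cases where
dropping cells pushes a gene below 3 detections, a second pass could remove
more genes — the pass is deliberately not iterated, so the output is a fixed
point of the *stated* order, not of repeated application.

Normalization rescales each cell to a common target library (median of
retained libraries by default — scale-stable and data-driven) and applies the
square root, a variance-stabilizing transform for counts. The squared values
of every cell then sum exactly to the target.

One consequence worth knowing: library-size normalization is compositional.
Strong planted (or real) up-shifts inflate their cells' libraries, which
pushes every *other* gene's normalized values slightly down; with enough cells
the highest-expression genes can cross the DEG gate as weak "down" calls.
This is a faithful property of library-normalized differential expression, not
an artifact of the EMD — analyses with many strong one-sided changes should
interpret weak opposite-direction calls among high expressors accordingly.

## Graph and diffusion imputation

A deliberately simplified stand-in for the batch-balanced kNN + MAGIC
combination: cells are embedded by PCA (full SVD, deterministic sign
convention: each component's largest-|loading| entry is positive), each cell
is connected to its k = 3 nearest neighbors (Euclidean in PC space, self
excluded, exact ties broken by ascending cell index) within every group when
balanced, and expression is smoothed by `T^t X` where `T` is the
row-normalized symmetrized adjacency and `t` = 3 (a customary diffusion
depth). Defaults: 50 PCs (configurable up to 100). Approximate-NN internals,
connectivity weighting, and adaptive diffusion kernels of the original tools
are intentionally not reproduced; what is kept is the testable essence —
group-balanced neighborhoods and powered row-stochastic diffusion.

DE runs on the normalized layer by default; `use_imputed` switches to the
diffused layer. Imputation shares information across neighboring cells, which
smooths distributions and inflates nominal significance; treat imputed-layer
p-values as ordering devices rather than calibrated error rates.

## Gene-set statistics

Overlap significance is the upper-tail hypergeometric probability
`P(X ≥ k)` with `k` the overlap within a stated universe; the universe should
be the genes actually tested in the DE run that produced the query list, and
genes outside it are dropped with a logged count. GMT-based
overrepresentation analysis applies this test per term with BH adjustment
across terms (significant ⇔ adjusted p < 0.05). UpSet-style tables report
exclusive intersections: each element of the union is assigned to exactly the
combination of sets containing it, so the counts partition the union.

## Population distances

Populations ((cell type, group) pairs by default) are summarized by their
centroid in PC space; similarity is the Euclidean distance between centroids,
clustered agglomeratively (average linkage by default; single, complete and
Ward available via Lance–Williams updates). Whether to cluster cells or
centroids, the PC count, and the linkage are genuinely open choices;
centroids + average linkage in a 50-PC embedding were chosen as the most
common reading of "Euclidean transcriptional distance among populations" and
because centroid recovery is directly testable against planted geometry. Ties
in merge order break deterministically toward the smallest (node_a, node_b)
pair. The merge tree exports as Newick and as a TSV of
(node_a, node_b, height, size) rows in scipy numbering.

## Synthetic data generator

Counts are negative binomial with `Var = μ + μ²/k` (mean/dispersion
parameterization, the standard scRNA-seq count model), gene baseline means
drawn log-normally and shared across populations. Defaults, chosen once as a
realistic regime and documented here because the generator defines the study
conditions:

| parameter | default | rationale |
|---|---|---|
| `nb_dispersion` k | 10 | UMI counts are modestly overdispersed; per-gene size estimates of 2–20 are typical after deduplication |
| `baseline_logmean_mu`, `sigma` | ln 1.0, 1.0 | mostly low-expressed genes with a high-expression tail |
| `mito_fraction_mean` | 0.02 | healthy-nucleus regime, well under the 5 % QC gate |
| validation studies | mean 5 (σ = 0.4), 2 000 genes, 200 cells/group | moderately expressed genes where a ×2 shift is comfortably detectable at this depth; 200 cells/group and the ×2 / 30 %-×3 effect sizes are the validation design |

Mitochondrial genes (the last `n_mito_genes`, `mt-`-prefixed) have their
baseline means rescaled so their expected library share equals
`mito_fraction_mean`. Effects: `shift` multiplies the NB mean for all cells of
the target population; `subpop_shift` multiplies it for a pre-drawn random
subset of exactly `ceil(fraction · n)` cells (membership drawn once per
effect/population before count sampling, so analyses can condition on it);
`scale` divides the dispersion by the magnitude — a pure spread change with
|EMD| > 0 and log2FC ≈ 0. An optional doublet flag mixes two random cells'
mean vectors 50/50 (off by default; no detector is provided).

What the generator does **not** emulate: ambient RNA, batch effects,
gene–gene correlation, zero-inflation beyond NB, depth variation across
cells beyond what NB sampling induces. Passing validation therefore
demonstrates the statistical machinery under a clean NB regime, not
robustness to those real-data pathologies.

Validation problem sizes (2 000 genes × 400 cells × 20 null seeds; 5 power
seeds; 100 geometry replicates of 300 cells × 300 genes; a 3 000-cell ×
1 000-gene demo pipeline) were chosen so the whole suite runs in well under a
minute per study on one CPU while keeping Monte-Carlo error far from the
decision thresholds.

## Reproducibility

Every stochastic step derives its stream from an explicit seed; the pipeline
derives per-stage seeds from the global seed plus fixed stage offsets. Run
manifests record the config (hashed), seeds and per-stage row counts, and
contain no timestamps, so identical configs produce byte-identical run
directories. DE tables are written at full float precision and read back with
round-trip parsing.

## Known limitations

- The asymptotic rank-test p is anti-conservative for very small groups; the
  `min_cells_per_group = 20` floor keeps the pipeline out of that regime.
- `n_total = n_up + n_down` in DEG summaries: a gene passing both gates with
  an exactly zero mean difference has no direction and is excluded from the
  totals (measure-zero on continuous layers).
- The hypergeometric ORA tests enrichment (upper tail) only.
- Population-distance significance (bootstrap support for dendrogram
  topology) is not computed.
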