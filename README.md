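# emdiff

Distribution-based differential expression for single-nucleus RNA-seq.

In single-cell and single-nucleus data, biologically meaningful expression
changes are often heterogeneous: a gene shifts in only a subpopulation of a
cell type, or its spread changes while the mean barely moves. Tests that
compare only group means under-report such changes. `emdiff` implements a
differential-expression procedure built around the **earth mover's distance
(EMD)** — the first-order 1-D Wasserstein distance between the per-gene
expression distributions of two groups of cells — combined with a
rank-sum significance test, for analysts running per-cell-type case/control
comparisons across genotypes, ages and treatments.

## The statistic

For gene *g* in one cell type, with expression samples *x* (reference group)
and *y* (condition group) on a common layer (square-root of library-size
normalized counts, or its graph-imputed version):

- **EMD**: `W₁(x, y) = ∫ |F_x(v) − F_y(v)| dv`, the area between the empirical
  CDFs; for equal sample sizes this is the mean absolute difference of the
  sorted samples. The sign is the sign of `mean(y) − mean(x)`.
- **p**: two-sided Mann–Whitney U with midrank ties, tie-corrected variance
  and continuity correction, Benjamini–Hochberg adjusted across the genes of
  one (cell type, contrast).
- **log2FC**: `log2((mean(y)+ε)/(mean(x)+ε))`, ε = 0.01.

A gene is called differentially expressed when it passes the joint gate

```
p_adj < 0.01   and   |EMD| ≥ 0.1
```

Around the core statistic the package provides: 10x-format (MatrixMarket)
readers/writers, the standard QC filters (genes in < 3 nuclei; cells with
< 500 detected genes or > 5 % mitochondrial counts), square-root library-size
normalization, a group-balanced kNN graph with row-stochastic diffusion
imputation (a documented, simplified stand-in for BBKNN + MAGIC),
nuclei-count-equalizing subsampling, hypergeometric gene-set overlap / GMT
overrepresentation analysis, UpSet-style exclusive intersections, PC-space
population-centroid distances with agglomerative clustering, and a synthetic
snRNA-seq generator with planted ground-truth effects.

## Worked example

```python
import numpy as np
from emdiff import (SimConfig, EffectSpec, generate_dataset, normalize_sqrt,
                    Contrast, EMDDifferentialExpression)

cfg = SimConfig(
    n_genes=1000, n_mito_genes=13,
    cell_types=("neuron",), groups=("WT", "MUT"),
    cells_per_population=200,
    baseline_logmean_mu=float(np.log(5.0)), baseline_logmean_sigma=0.4,
    nb_dispersion=10.0,
    effects=(
        # homogeneous mean shift: every MUT neuron doubles its mean
        EffectSpec(gene=0, cell_type="neuron", group="MUT",
                   kind="shift", magnitude=2.0),
        # heterogeneous shift: only 30% of MUT neurons triple their mean
        EffectSpec(gene=1, cell_type="neuron", group="MUT",
                   kind="subpop_shift", magnitude=3.0, affected_fraction=0.3),
    ),
    seed=7,
)
counts, metadata, truth = generate_dataset(cfg)
expr = normalize_sqrt(counts)
model = EMDDifferentialExpression(expr, metadata,
                                  Contrast("neuron", "WT", "MUT"))
results = model.fit()
print(results.summary())
```

prints

```
EMD differential expression
============================================================
cell type:        neuron
contrast:         MUT vs WT (reference)
layer:            normalized_sqrt
cells:            200 ref / 200 alt
genes tested:     1000
gate:             p_adj < 0.01 and |EMD| >= 0.1
DEGs:             2 (2 up, 0 down)
------------------------------------------------------------
top genes by |EMD|:
gene            signed_emd       p_adj    log2fc  call
Gene00000           0.9056    1.73e-27     0.511  up
Gene00001           0.5438    0.000298     0.308  up
Gene00812          -0.2015       0.764    -0.147  -
...
```

Both planted genes — and only they — pass the joint gate. The homogeneous
shift (Gene00000) has the larger fold change; the subpopulation shift
(Gene00001) is flagged with a fold change 40 % smaller, which is the point of
using a distribution distance: the change lives in 30 % of the cells, so the
mean moves little while the CDFs separate clearly. `results.table` holds the
full per-gene frame (`emd, signed_emd, u_stat, p_raw, p_adj, log2fc, is_deg,
direction`), sorted by descending |EMD|.

The same analysis is available from the shell:

```sh
emdiff simulate --config sim.yaml --seed 7 --out data/
emdiff de --input data/ --metadata data/metadata.tsv --contrast MUT:WT --out de/
emdiff distance --input data/ --metadata data/metadata.tsv --out dist/
emdiff run-all --config pipeline.yaml        # everything, reproducibly
```

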