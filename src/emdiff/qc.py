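"""Quality-control filters and normalization.

The QC pass is single and order-fixed: (1) drop genes detected (count > 0) in
fewer than ``min_cells_per_gene`` cells; (2) on the gene-filtered matrix, drop
cells detecting fewer than ``min_genes_per_cell`` genes; (3) drop cells whose
mitochondrial share of total counts — computed on the gene-filtered matrix —
exceeds ``max_mito_frac`` (strictly "more than"; equality is retained unless
``mito_inclusive`` is set).

Normalization rescales each cell to a common library size (median of retained
libraries by default) and square-root-transforms, so for every non-empty cell
the squared values sum to ``target_sum``.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .containers import CountMatrix, ExpressionMatrix


def apply_qc_filters(
    cm: CountMatrix,
    min_cells_per_gene: int = 3,
    min_genes_per_cell: int = 500,
    max_mito_frac: float = 0.05,
    mito_inclusive: bool = False,
):
    """Apply the fixed-order QC pass; returns (filtered CountMatrix, report dict).

    The report lists retained and dropped gene/cell identifiers with the reason
    for each drop (``low_detection`` genes; ``few_genes`` / ``high_mito`` cells,
    first applicable reason wins).
    """
    counts = cm.counts
    detected = counts.copy()
    detected.data = np.ones_like(detected.data)

    cells_per_gene = np.asarray(detected.sum(axis=0)).ravel()
    gene_keep = cells_per_gene >= min_cells_per_gene

    sub = counts[:, gene_keep].tocsr()
    genes_per_cell = np.asarray((sub > 0).sum(axis=1)).ravel()
    total = np.asarray(sub.sum(axis=1)).ravel().astype(float)
    mito_counts = np.asarray(
        sub[:, cm.is_mito[gene_keep]].sum(axis=1)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_share = np.where(total > 0, mito_counts / np.maximum(total, 1), 0.0)

    few_genes = genes_per_cell < min_genes_per_cell
    if mito_inclusive:
        high_mito = mito_share >= max_mito_frac
    else:
        high_mito = mito_share > max_mito_frac
    cell_keep = ~(few_genes | high_mito)
    if not cell_keep.any():
        raise ValueError("empty after QC: every cell was removed")

    reasons = np.where(few_genes, "few_genes",
                       np.where(high_mito, "high_mito", ""))
    report = {
        "n_genes_in": cm.n_genes,
        "n_cells_in": cm.n_cells,
        "n_genes_retained": int(gene_keep.sum()),
        "n_cells_retained": int(cell_keep.sum()),
        "genes_dropped": {
            str(g): "low_detection"
            for g in cm.gene_ids[~gene_keep]
        },
        "cells_dropped": {
            str(b): r
            for b, r in zip(cm.cell_barcodes[~cell_keep], reasons[~cell_keep])
            if r
        },
        "thresholds": {
            "min_cells_per_gene": min_cells_per_gene,
            "min_genes_per_cell": min_genes_per_cell,
            "max_mito_frac": max_mito_frac,
            "mito_inclusive": mito_inclusive,
        },
    }
    out = CountMatrix(
        counts=sub[cell_keep],
        gene_ids=cm.gene_ids[gene_keep],
        gene_names=cm.gene_names[gene_keep],
        cell_barcodes=cm.cell_barcodes[cell_keep],
        is_mito=cm.is_mito[gene_keep],
    )
    return out, report


def normalize_sqrt(cm: CountMatrix, target_sum="median") -> ExpressionMatrix:
    """Library-size normalize to ``target_sum`` and square-root transform.

    value[c, g] = sqrt(count[c, g] * target_sum / library[c]). ``"median"``
    resolves to the median library size over the given cells.
    """
    lib = cm.library_sizes().astype(float)
    if (lib <= 0).any():
        bad = cm.cell_barcodes[lib <= 0][0]
        raise ValueError(
            f"cell {bad!r} has zero library size; run QC before normalizing"
        )
    if target_sum == "median":
        target = float(np.median(lib))
    else:
        target = float(target_sum)
        if target <= 0:
            raise ValueError("target_sum must be positive")
    scale = sp.diags(target / lib)
    values = scale @ cm.counts.astype(float)
    values = values.tocsr()
    values.data = np.sqrt(values.data)
    return ExpressionMatrix(
        values=values,
        gene_ids=cm.gene_ids,
        gene_names=cm.gene_names,
        cell_barcodes=cm.cell_barcodes,
        layer="normalized_sqrt",
        target_sum=target,
    )
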