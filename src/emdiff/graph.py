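"""PCA embedding, group-balanced kNN graph, and diffusion imputation.

This is a deliberately simple stand-in for the batch-balanced-kNN + MAGIC
combination used in large single-cell studies. It keeps the two essences that
matter downstream: every cell is connected to its k nearest neighbors *within
each experimental group* (so no group dominates a neighborhood), and expression
is smoothed by powering a row-stochastic transition operator built from that
graph. Approximate-NN internals, connectivity weighting and adaptive diffusion
kernels are intentionally not reproduced.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA

from .containers import Embedding, ExpressionMatrix, NeighborGraph


def compute_pca(expr, n_components: int = 50, center: bool = True) -> Embedding:
    """PCA of an expression layer with a deterministic sign convention.

    Each component is flipped, if needed, so its largest-|loading| entry is
    positive; output is then fully deterministic (full SVD solver).
    Accepts an :class:`ExpressionMatrix` or a dense array.
    """
    X = expr.dense() if isinstance(expr, ExpressionMatrix) else np.asarray(expr, float)
    n_cells, n_genes = X.shape
    if n_components > min(n_cells - 1, n_genes):
        raise ValueError(
            f"n_components={n_components} exceeds min(cells-1, genes)="
            f"{min(n_cells - 1, n_genes)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    if center:
        coords = pca.fit_transform(X)
    else:
        # components from the centered data, projection of the raw data
        pca.fit(X)
        coords = X @ pca.components_.T
    comps = pca.components_
    flip = np.sign(comps[np.arange(comps.shape[0]),
                         np.argmax(np.abs(comps), axis=1)])
    flip[flip == 0] = 1.0
    comps = comps * flip[:, None]
    coords = coords * flip[None, :]
    return Embedding(
        coords=coords,
        explained_variance=pca.explained_variance_.copy(),
        components=comps,
        mean=X.mean(axis=0) if center else np.zeros(n_genes),
    )


def build_knn_graph(emb: Embedding, metadata, k_per_group: int = 3,
                    balanced: bool = True) -> NeighborGraph:
    """Group-balanced kNN graph in PC space.

    For each cell, the ``k_per_group`` nearest cells (Euclidean, self excluded)
    are found within every group when ``balanced``; otherwise globally. Exact
    distance ties break by ascending cell index (stable sort). The transition
    operator is the row-normalized symmetrized adjacency (A + A^T).
    """
    coords = np.asarray(emb.coords, dtype=float)
    n = coords.shape[0]
    if len(metadata) != n:
        raise ValueError("metadata does not cover all embedded cells")
    groups = metadata["group"].to_numpy()
    group_labels = sorted(set(groups)) if balanced else ["__all__"]

    rows, cols = [], []
    neighbor_lists = [[] for _ in range(n)]
    for g in group_labels:
        idx_g = np.arange(n) if g == "__all__" else np.flatnonzero(groups == g)
        if len(idx_g) == 0:
            continue
        # chunked exact distances; stable argsort gives the ascending-index tie rule
        for start in range(0, n, 512):
            block = np.arange(start, min(start + 512, n))
            d = np.sqrt(
                np.maximum(
                    ((coords[block, None, :] - coords[None, idx_g, :]) ** 2).sum(-1),
                    0.0,
                )
            )
            # exclude self
            self_pos = {c: j for j, c in enumerate(idx_g)}
            for bi, cell in enumerate(block):
                j = self_pos.get(cell)
                if j is not None:
                    d[bi, j] = np.inf
                avail = len(idx_g) - (1 if j is not None else 0)
                k = min(k_per_group, avail)
                if k < k_per_group:
                    warnings.warn(
                        f"group {g!r} has only {avail} candidate neighbors "
                        f"(< k={k_per_group}); using all of them"
                    )
                if k <= 0:
                    continue
                order = np.argsort(d[bi], kind="stable")[:k]
                nb = idx_g[order]
                neighbor_lists[cell].extend(int(x) for x in nb)
                rows.extend([cell] * k)
                cols.extend(int(x) for x in nb)

    adj = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    ).tocsr()
    w = adj + adj.T
    rs = np.asarray(w.sum(axis=1)).ravel()
    rs[rs == 0] = 1.0
    transition = sp.diags(1.0 / rs) @ w
    return NeighborGraph(
        neighbors=np.array([np.array(sorted(nl)) for nl in neighbor_lists],
                           dtype=object),
        adjacency=adj,
        transition=transition.tocsr(),
        k_per_group=k_per_group,
        balanced=balanced,
        groups=tuple(group_labels),
    )


def diffusion_impute(expr: ExpressionMatrix, graph: NeighborGraph,
                     t: int = 3) -> ExpressionMatrix:
    """Smooth expression by ``t`` steps of the transition operator (T^t X).

    ``t = 0`` is the identity. Row-stochasticity of T makes constant genes
    invariant and the operation non-expansive in max-norm.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    X = expr.dense().copy()
    for _ in range(int(t)):
        X = graph.transition @ X
    return ExpressionMatrix(
        values=np.asarray(X),
        gene_ids=expr.gene_ids,
        gene_names=expr.gene_names,
        cell_barcodes=expr.cell_barcodes,
        layer="imputed",
        target_sum=expr.target_sum,
    )
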