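"""In-memory containers shared across the pipeline.

The pipeline passes around three kinds of matrices: raw UMI counts
(:class:`CountMatrix`), a real-valued expression layer derived from them
(:class:`ExpressionMatrix`, either library-size-normalized square-root counts or
their diffusion-imputed version), and a low-dimensional PCA embedding
(:class:`Embedding`). Cell annotations travel as a plain pandas DataFrame with
the columns ``barcode, cell_type, group, sample`` (validated by
:func:`validate_metadata`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

METADATA_COLUMNS = ("barcode", "cell_type", "group", "sample")


def _as_csr(m) -> sp.csr_matrix:
    if sp.issparse(m):
        return m.tocsr()
    return sp.csr_matrix(np.asarray(m))


@dataclass
class CountMatrix:
    """Cells x genes non-negative integer UMI counts with gene/cell identifiers.

    ``is_mito`` flags mitochondrial genes (case-insensitive ``mt-`` name prefix
    by convention; an explicit flag vector may be supplied instead).
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    gene_names: np.ndarray
    cell_barcodes: np.ndarray
    is_mito: np.ndarray = None

    def __post_init__(self):
        self.counts = _as_csr(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.cell_barcodes = np.asarray(self.cell_barcodes, dtype=object)
        n_cells, n_genes = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.gene_names) != n_genes:
            raise ValueError(
                f"gene annotation length mismatch: matrix has {n_genes} genes"
            )
        if len(self.cell_barcodes) != n_cells:
            raise ValueError(
                f"barcode length {len(self.cell_barcodes)} != {n_cells} cells"
            )
        if len(set(self.cell_barcodes)) != n_cells:
            raise ValueError("cell barcodes are not unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.is_mito is None:
            self.is_mito = mito_flags(self.gene_names)
        else:
            self.is_mito = np.asarray(self.is_mito, dtype=bool)
            if len(self.is_mito) != n_genes:
                raise ValueError("is_mito length mismatch")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()


def mito_flags(gene_names, prefix: str = "mt-") -> np.ndarray:
    """Flag mitochondrial genes by case-insensitive name prefix (default ``mt-``)."""
    p = prefix.lower()
    return np.array([str(g).lower().startswith(p) for g in gene_names], dtype=bool)


@dataclass
class ExpressionMatrix:
    """Cells x genes real-valued layer with provenance.

    ``layer`` is ``normalized_sqrt`` (square root of library-size-normalized
    counts) or ``imputed`` (after graph diffusion). For ``normalized_sqrt``,
    the squared values of every non-empty cell sum to ``target_sum``.
    """

    values: object  # csr matrix or ndarray, cells x genes
    gene_ids: np.ndarray
    gene_names: np.ndarray
    cell_barcodes: np.ndarray
    layer: str = "normalized_sqrt"
    target_sum: float = float("nan")

    def __post_init__(self):
        if not sp.issparse(self.values):
            self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.cell_barcodes = np.asarray(self.cell_barcodes, dtype=object)
        if self.layer not in ("normalized_sqrt", "imputed"):
            raise ValueError(f"unknown layer {self.layer!r}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return self.values

    def subset_cells(self, idx) -> np.ndarray:
        """Dense (len(idx) x genes) view of the selected cells."""
        sub = self.values[idx]
        if sp.issparse(sub):
            return np.asarray(sub.todense(), dtype=float)
        return np.asarray(sub, dtype=float)


@dataclass
class Embedding:
    """PCA embedding: per-cell coordinates plus component loadings."""

    coords: np.ndarray  # cells x n_components
    explained_variance: np.ndarray
    components: np.ndarray  # n_components x genes
    mean: np.ndarray  # per-gene centering vector

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]


@dataclass
class NeighborGraph:
    """Group-balanced kNN graph and its row-stochastic transition operator."""

    neighbors: np.ndarray  # object array: per cell, array of neighbor indices
    adjacency: sp.csr_matrix
    transition: sp.csr_matrix
    k_per_group: int
    balanced: bool = True
    groups: tuple = field(default_factory=tuple)


def validate_metadata(metadata: pd.DataFrame, barcodes=None) -> pd.DataFrame:
    """Check the metadata contract: required columns, unique barcodes.

    If ``barcodes`` (the matrix's cell barcodes) is given, metadata rows whose
    barcode is absent from the matrix are dropped with a warning count attached
    to the returned frame's ``attrs['n_unknown_barcodes']``.
    """
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    if metadata["barcode"].duplicated().any():
        dup = metadata.loc[metadata["barcode"].duplicated(), "barcode"].iloc[0]
        raise ValueError(f"duplicated barcode in metadata: {dup!r}")
    out = metadata.reset_index(drop=True)
    n_unknown = 0
    if barcodes is not None:
        known = set(barcodes)
        keep = out["barcode"].isin(known)
        n_unknown = int((~keep).sum())
        out = out.loc[keep].reset_index(drop=True)
    out.attrs["n_unknown_barcodes"] = n_unknown
    return out
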