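"""Readers and writers for the standard on-disk formats.

The 10x dialect is used for count matrices: ``matrix.mtx`` (MatrixMarket
coordinate, stored genes x cells as CellRanger writes it), ``features.tsv``
(gene_id, gene_name, feature_type) and ``barcodes.tsv``, each optionally
gzipped. Matrices are always oriented cells x genes in memory.
"""

from __future__ import annotations

import gzip
import json
import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix, validate_metadata

DE_TABLE_COLUMNS = [
    "gene_id", "gene_name", "n_ref", "n_alt", "emd", "signed_emd", "u_stat",
    "p_raw", "p_adj", "log2fc", "is_deg", "direction",
]


def _find(directory, stem):
    for name in (stem, stem + ".gz"):
        p = os.path.join(directory, name)
        if os.path.exists(p):
            return p
    raise FileNotFoundError(
        f"missing {stem}(.gz) in {directory!r}"
    )


def _open_text(path):
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _open_binary(path):
    if path.endswith(".gz"):
        return gzip.open(path, "rb")
    return open(path, "rb")


def read_tenx_mtx(directory: str) -> CountMatrix:
    """Read a 10x-style directory into a cells x genes :class:`CountMatrix`.

    The on-disk matrix is genes x cells (CellRanger orientation) and is
    transposed on load. Mitochondrial genes are flagged by the
    case-insensitive ``mt-`` gene-name prefix.
    """
    mtx_path = _find(directory, "matrix.mtx")
    feat_path = _find(directory, "features.tsv")
    bc_path = _find(directory, "barcodes.tsv")
    with _open_binary(mtx_path) as fh:
        m = scipy.io.mmread(fh)
    feats = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    if feats.shape[1] < 2:
        raise ValueError(f"features file {feat_path!r} needs >= 2 columns")
    with _open_text(bc_path) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    n_genes, n_cells = m.shape
    if n_genes != len(feats):
        raise ValueError(
            f"matrix header says {n_genes} genes but features.tsv has "
            f"{len(feats)} lines"
        )
    if n_cells != len(barcodes):
        raise ValueError(
            f"matrix header says {n_cells} cells but barcodes.tsv has "
            f"{len(barcodes)} lines"
        )
    counts = sp.csr_matrix(m.T)
    counts.data = np.rint(counts.data).astype(np.int64)
    return CountMatrix(
        counts=counts,
        gene_ids=feats.iloc[:, 0].to_numpy(dtype=object),
        gene_names=feats.iloc[:, 1].to_numpy(dtype=object),
        cell_barcodes=np.array(barcodes, dtype=object),
    )


def write_tenx_mtx(cm: CountMatrix, directory: str) -> None:
    """Write a CountMatrix as a plain-text 10x-style directory (genes x cells)."""
    os.makedirs(directory, exist_ok=True)
    scipy.io.mmwrite(
        os.path.join(directory, "matrix.mtx"),
        sp.coo_matrix(cm.counts.T.astype(np.int64)),
        field="integer",
    )
    feats = pd.DataFrame({
        "gene_id": cm.gene_ids,
        "gene_name": cm.gene_names,
        "feature_type": "Gene Expression",
    })
    feats.to_csv(os.path.join(directory, "features.tsv"),
                 sep="\t", header=False, index=False)
    with open(os.path.join(directory, "barcodes.tsv"), "w") as fh:
        for bc in cm.cell_barcodes:
            fh.write(f"{bc}\n")


def read_cell_metadata(path: str, barcodes=None) -> pd.DataFrame:
    """Read metadata TSV (barcode, cell_type, group, sample); unknown barcodes
    (absent from ``barcodes``) are dropped and counted in ``attrs``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_metadata(df, barcodes)


def write_cell_metadata(metadata: pd.DataFrame, path: str) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def write_de_table(table: pd.DataFrame, path: str) -> None:
    """Write a DE result table with the fixed column order, full precision."""
    cols = [c for c in DE_TABLE_COLUMNS if c in table.columns]
    table[cols].to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_de_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_qc_report(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_gmt(path: str) -> dict:
    """Read a GMT gene-set file into ``{term: (description, frozenset(genes))}``.

    Lines are tab-separated ``term, description, gene...``; duplicate genes
    within a term are deduplicated; duplicate term names are an error.
    """
    collection = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs term, description and "
                    f">= 1 gene ({len(parts)} fields found)"
                )
            term, desc, genes = parts[0], parts[1], parts[2:]
            if term in collection:
                raise ValueError(f"{path}:{lineno}: duplicate term {term!r}")
            gene_set = frozenset(g for g in genes if g)
            if not gene_set:
                raise ValueError(f"{path}:{lineno}: term {term!r} has no genes")
            collection[term] = (desc, gene_set)
    return collection


def write_gmt(collection: dict, path: str) -> None:
    with open(path, "w") as fh:
        for term in collection:
            desc, genes = collection[term]
            fh.write("\t".join([term, desc] + sorted(genes)) + "\n")
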