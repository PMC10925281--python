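"""Readers and writers for the on-disk formats the pipeline touches.

Count matrices travel as MatrixMarket coordinate files (genes as rows, cells
as columns, 1-based indices on disk) next to one-entry-per-line gene and
barcode TSVs, the 10x convention. Gene/barcode files may carry extra
tab-separated columns (as 10x ``features.tsv`` does); only the first column
is used. Tabular results (DE records, candidate tables, ddPCR plates, cross
counts) are plain CSV via pandas.
"""

from __future__ import annotations

import logging
import sys

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import FormatError, GeneExpressionMatrix

logger = logging.getLogger("rdnamag")


def setup_logging(level: str = "INFO") -> None:
    """Log to stderr; result data only ever goes to files."""
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def read_id_list(path) -> list:
    """First tab-separated column of a one-entry-per-line file."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def write_id_list(ids, path) -> None:
    with open(path, "w") as fh:
        for x in ids:
            fh.write(f"{x}\n")


def read_counts_mtx(matrix_path, genes_path, barcodes_path, cell_meta=None) -> GeneExpressionMatrix:
    """Read a MatrixMarket counts file with its gene/barcode TSVs.

    Raises :class:`FormatError` when the declared matrix dimensions disagree
    with the TSV lengths or when entries are negative or non-integer.
    """
    genes = read_id_list(genes_path)
    barcodes = read_id_list(barcodes_path)
    try:
        mat = scipy.io.mmread(matrix_path)
    except Exception as exc:  # malformed header / body
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    mat = sp.coo_matrix(mat)
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix header declares {mat.shape} but TSVs list "
            f"{len(genes)} genes and {len(barcodes)} barcodes"
        )
    if mat.nnz:
        if not np.issubdtype(mat.data.dtype, np.integer):
            if not np.all(np.equal(np.mod(mat.data, 1), 0)):
                raise FormatError("matrix contains non-integer values")
            mat = mat.astype(np.int64)
        if mat.data.min() < 0:
            raise FormatError("matrix contains negative values")
    return GeneExpressionMatrix(genes, barcodes, mat.tocsr(), cell_meta=cell_meta)


def write_counts_mtx(matrix: GeneExpressionMatrix, matrix_path, genes_path, barcodes_path) -> None:
    """Write counts + id files in the layout :func:`read_counts_mtx` reads."""
    scipy.io.mmwrite(str(matrix_path), matrix.counts.tocoo(), field="integer")
    write_id_list(matrix.gene_ids, genes_path)
    write_id_list(matrix.cell_barcodes, barcodes_path)


def read_cell_meta(path) -> pd.DataFrame:
    """Per-cell metadata CSV with a ``barcode`` column as index."""
    meta = pd.read_csv(path)
    if "barcode" not in meta.columns:
        raise FormatError("cell metadata CSV must have a 'barcode' column")
    return meta.set_index("barcode")


def write_cell_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index=True, index_label="barcode")


def read_ddpcr_plate(path) -> pd.DataFrame:
    """ddPCR plate CSV: sample, target, droplets_total, droplets_positive."""
    df = pd.read_csv(path)
    required = {"sample", "target", "droplets_total", "droplets_positive"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"ddPCR plate CSV missing columns: {sorted(missing)}")
    return df


def read_cross_counts(path) -> pd.DataFrame:
    """Cross-offspring CSV: label, n_wildtype, n_bobbed, n_excluded."""
    df = pd.read_csv(path)
    required = {"label", "n_wildtype", "n_bobbed"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"cross counts CSV missing columns: {sorted(missing)}")
    if "n_excluded" not in df.columns:
        df["n_excluded"] = 0
    return df
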