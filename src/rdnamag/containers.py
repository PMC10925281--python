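"""Core in-memory container for gene-by-cell count data.

The pipeline operates on sparse integer count matrices with genes as rows
and cells as columns (the 10x on-disk convention), plus a per-cell metadata
table carrying the experimental condition (low vs normal rDNA copy number)
and, once computed, cluster ids and cell-type labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

LOW_RDNA = "low_rDNA"
NORMAL_RDNA = "normal_rDNA"
CONDITIONS = (LOW_RDNA, NORMAL_RDNA)


class FormatError(ValueError):
    """Raised when an on-disk file does not satisfy the expected format."""


class ValidationError(ValueError):
    """Raised when a container or configuration violates its invariants."""


@dataclass
class GeneExpressionMatrix:
    """Sparse integer gene x cell count matrix with aligned identifiers.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene identifiers, one per matrix row.
    cell_barcodes : list of str
        Unique cell barcodes, one per matrix column.
    counts : scipy.sparse matrix
        Non-negative integer counts, shape ``(len(gene_ids), len(cell_barcodes))``.
    cell_meta : pandas.DataFrame, optional
        Indexed by barcode; recognised columns are ``condition``
        (one of ``low_rDNA`` / ``normal_rDNA``), ``cluster`` and ``cell_type``.
        Reindexed to ``cell_barcodes`` on construction.
    """

    gene_ids: list
    cell_barcodes: list
    counts: sp.spmatrix
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        self.cell_barcodes = list(self.cell_barcodes)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("gene_ids must be unique")
        if len(set(self.cell_barcodes)) != len(self.cell_barcodes):
            raise ValidationError("cell_barcodes must be unique")
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_barcodes)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.cell_barcodes)} cells)"
            )
        if self.counts.nnz:
            data = self.counts.data
            if not np.issubdtype(data.dtype, np.integer):
                if not np.all(np.equal(np.mod(data, 1), 0)):
                    raise ValidationError("counts must be integers")
                self.counts = self.counts.astype(np.int64)
            if self.counts.data.min(initial=0) < 0:
                raise ValidationError("counts must be non-negative")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_barcodes, name="barcode"))
        else:
            extra = set(self.cell_meta.index) - set(self.cell_barcodes)
            if extra:
                raise ValidationError(
                    f"cell_meta contains barcodes absent from the matrix: {sorted(extra)[:5]}"
                )
            self.cell_meta = self.cell_meta.reindex(self.cell_barcodes)
            self.cell_meta.index.name = "barcode"

    # -- basic queries -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_barcodes)

    def counts_per_cell(self) -> np.ndarray:
        """Total counts (library size) per cell."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def features_per_cell(self) -> np.ndarray:
        """Number of detected (nonzero) genes per cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present in matrix") from None

    def gene_counts(self, gene: str) -> np.ndarray:
        """Dense per-cell raw counts of one gene."""
        return np.asarray(self.counts[self.gene_index(gene)].todense()).ravel()

    def barcode_positions(self, barcodes) -> np.ndarray:
        lookup = {b: i for i, b in enumerate(self.cell_barcodes)}
        try:
            return np.array([lookup[b] for b in barcodes], dtype=int)
        except KeyError as exc:
            raise KeyError(f"barcode {exc.args[0]!r} not present in matrix") from None

    # -- subsetting ----------------------------------------------------

    def subset_cells(self, barcodes) -> "GeneExpressionMatrix":
        """Restrict to the given barcodes, preserving current column order."""
        keep = set(barcodes)
        order = [b for b in self.cell_barcodes if b in keep]
        idx = self.barcode_positions(order)
        return GeneExpressionMatrix(
            gene_ids=self.gene_ids,
            cell_barcodes=order,
            counts=self.counts[:, idx],
            cell_meta=self.cell_meta.loc[order],
        )

    def equals(self, other: "GeneExpressionMatrix") -> bool:
        return (
            self.gene_ids == other.gene_ids
            and self.cell_barcodes == other.cell_barcodes
            and (self.counts != other.counts).nnz == 0
        )
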