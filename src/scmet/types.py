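"""Core in-memory containers.

``CellMatrix`` holds a raw single-cell count matrix (cells x genes, sparse)
with barcodes, gene symbols and optional per-cell type labels; ``BulkProfile``
holds one bulk RNA-seq sample. Both validate their invariants on
construction so downstream stages can assume well-formed inputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import ConsistencyError, ParameterError

MITO_PREFIX = "MT-"


def mito_mask(genes: np.ndarray, prefix: str = MITO_PREFIX,
              gene_list: list[str] | None = None) -> np.ndarray:
    """Boolean mask of mitochondrial genes.

    Genes are matched case-insensitively against ``prefix`` by default; an
    explicit ``gene_list`` overrides the prefix rule entirely.
    """
    genes = np.asarray(genes, dtype=object)
    if gene_list is not None:
        wanted = set(gene_list)
        return np.array([g in wanted for g in genes], dtype=bool)
    pref = prefix.upper()
    return np.array([str(g).upper().startswith(pref) for g in genes], dtype=bool)


@dataclass
class CellMatrix:
    """Sparse raw-count matrix with cell and gene annotations.

    Parameters
    ----------
    counts
        Nonnegative integer counts, cells x genes (any scipy sparse or dense
        array; stored as CSR).
    barcodes
        Unique cell identifiers, one per row.
    genes
        Unique gene symbols, one per column.
    labels
        Optional per-cell type annotation.
    mito_prefix
        Prefix identifying mitochondrial genes (case-insensitive), used to
        derive :attr:`mito_mask`.
    """

    counts: sp.csr_matrix
    barcodes: np.ndarray
    genes: np.ndarray
    labels: np.ndarray | None = None
    mito_prefix: str = MITO_PREFIX
    mito_genes: list[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        self.genes = np.asarray(self.genes, dtype=object)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
        self._validate()

    def _validate(self) -> None:
        n, g = self.counts.shape
        if len(self.barcodes) != n:
            raise ConsistencyError(
                f"counts has {n} cells but {len(self.barcodes)} barcodes")
        if len(self.genes) != g:
            raise ConsistencyError(
                f"counts has {g} genes but {len(self.genes)} gene names")
        if len(set(self.barcodes)) != n:
            raise ConsistencyError("barcodes are not unique")
        if len(set(self.genes)) != g:
            raise ConsistencyError("gene names are not unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ParameterError("counts must be nonnegative")
        if self.labels is not None and len(self.labels) != n:
            raise ConsistencyError(
                f"{len(self.labels)} labels for {n} cells")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def mito_mask(self) -> np.ndarray:
        return mito_mask(self.genes, self.mito_prefix, self.mito_genes)

    def subset_cells(self, keep: np.ndarray) -> "CellMatrix":
        """Row subset preserving input order; ``keep`` is a bool mask or index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CellMatrix(
            counts=self.counts[keep],
            barcodes=self.barcodes[keep],
            genes=self.genes,
            labels=None if self.labels is None else self.labels[keep],
            mito_prefix=self.mito_prefix,
            mito_genes=self.mito_genes,
        )

    def subset_genes(self, keep: np.ndarray) -> "CellMatrix":
        """Column subset preserving input order."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CellMatrix(
            counts=self.counts[:, keep],
            barcodes=self.barcodes,
            genes=self.genes[keep],
            labels=self.labels,
            mito_prefix=self.mito_prefix,
            mito_genes=self.mito_genes,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CellMatrix):
            return NotImplemented
        same_labels = (
            (self.labels is None and other.labels is None)
            or (self.labels is not None and other.labels is not None
                and np.array_equal(self.labels, other.labels))
        )
        return (
            self.counts.shape == other.counts.shape
            and (self.counts != other.counts).nnz == 0
            and np.array_equal(self.barcodes, other.barcodes)
            and np.array_equal(self.genes, other.genes)
            and same_labels
        )


@dataclass
class BulkProfile:
    """One bulk RNA-seq sample: a per-gene nonnegative expression vector."""

    sample_id: str
    values: np.ndarray
    genes: np.ndarray
    unit: str = "counts"  # "counts" or "tpm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.genes = np.asarray(self.genes, dtype=object)
        if self.unit not in ("counts", "tpm"):
            raise ParameterError(f"unit must be 'counts' or 'tpm', got {self.unit!r}")
        if len(self.values) != len(self.genes):
            raise ConsistencyError(
                f"{len(self.values)} values for {len(self.genes)} genes")
        if len(set(self.genes)) != len(self.genes):
            raise ConsistencyError("bulk gene names are not unique")
        if np.any(self.values < 0):
            raise ParameterError("bulk values must be nonnegative")
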