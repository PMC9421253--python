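"""Core in-memory containers for the analysis.

The package works on three objects throughout:

``CountMatrix``
    Raw droplet counts, cells x genes, with per-cell metadata
    (``sample_id``, ``mutation_group``, optional ground-truth columns).
``NormalizedMatrix``
    Library-size normalized, log-transformed expression with the
    normalization parameters kept as provenance.
``GeneAnnotation``
    Genomic coordinates per gene (1-based inclusive, GTF-style) defining
    the within-chromosome gene order that copy-number smoothing relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["CountMatrix", "NormalizedMatrix", "GeneAnnotation", "FormatError"]


class FormatError(ValueError):
    """Raised when an input file or container violates the format contract."""


def _as_str_array(values: Sequence[str]) -> np.ndarray:
    return np.asarray(list(values), dtype=object)


@dataclass
class CountMatrix:
    """Sparse non-negative integer cell x gene count matrix.

    Parameters
    ----------
    values
        Sparse matrix of raw counts, shape ``(n_cells, n_genes)``.
    cell_ids, gene_ids
        Unique barcode / gene-symbol strings aligned to the matrix axes.
    cell_meta
        One row per cell, aligned by order. Expected columns include
        ``sample_id`` and ``mutation_group`` (``RET``, ``SDHB`` or ``NA``);
        synthetic cohorts additionally carry ``true_cell_type`` and
        ``true_program_ids``.
    """

    values: sp.spmatrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.cell_ids = _as_str_array(self.cell_ids)
        self.gene_ids = _as_str_array(self.gene_ids)
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=range(len(self.cell_ids)))
        self.cell_meta = self.cell_meta.reset_index(drop=True)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        n_cells, n_genes = self.values.shape
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"cell_ids length {len(self.cell_ids)} != matrix rows {n_cells}"
            )
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"gene_ids length {len(self.gene_ids)} != matrix columns {n_genes}"
            )
        if len(set(self.cell_ids)) != n_cells:
            raise FormatError("duplicate cell barcodes")
        if len(set(self.gene_ids)) != n_genes:
            raise FormatError("duplicate gene ids")
        if len(self.cell_meta) != n_cells:
            raise FormatError(
                f"cell_meta has {len(self.cell_meta)} rows for {n_cells} cells"
            )
        data = self.values.data
        if data.size:
            if np.any(data < 0):
                raise FormatError("negative count encountered")
            if not np.allclose(data, np.round(data)):
                raise FormatError("non-integer count encountered")

    # -- conveniences --------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        """Return a new CountMatrix keeping cells where ``mask`` is True
        (or at integer positions if ``mask`` is an index array)."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            values=self.values[idx],
            cell_ids=self.cell_ids[idx],
            gene_ids=self.gene_ids,
            cell_meta=self.cell_meta.iloc[idx].reset_index(drop=True),
        )

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = np.array([pos[g] for g in genes], dtype=int)
        return CountMatrix(
            values=self.values[:, idx],
            cell_ids=self.cell_ids,
            gene_ids=self.gene_ids[idx],
            cell_meta=self.cell_meta,
        )

    def detected_genes_per_cell(self) -> np.ndarray:
        """Number of genes with a nonzero count in each cell (nFeature)."""
        return np.asarray((self.values > 0).sum(axis=1)).ravel()


@dataclass
class NormalizedMatrix:
    """Log-normalized expression, cells x genes.

    ``values`` holds ``ln(1 + count/total * scale_total)``; ``provenance``
    records ``scale_total``, ``pseudocount`` and ``log_base`` so the
    transform is recoverable.
    """

    values: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    cell_meta: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sp.issparse(self.values):
            self.values = np.asarray(self.values.todense())
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = _as_str_array(self.cell_ids)
        self.gene_ids = _as_str_array(self.gene_ids)
        self.cell_meta = self.cell_meta.reset_index(drop=True)
        if np.any(self.values < 0):
            raise FormatError("normalized values must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return np.array([pos[g] for g in genes], dtype=int)

    def subset_cells(self, mask: np.ndarray) -> "NormalizedMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return NormalizedMatrix(
            values=self.values[idx],
            cell_ids=self.cell_ids[idx],
            gene_ids=self.gene_ids,
            cell_meta=self.cell_meta.iloc[idx].reset_index(drop=True),
            provenance=dict(self.provenance),
        )

    def subset_genes(self, genes: Sequence[str]) -> "NormalizedMatrix":
        idx = self.gene_index(genes)
        return NormalizedMatrix(
            values=self.values[:, idx],
            cell_ids=self.cell_ids,
            gene_ids=self.gene_ids[idx],
            cell_meta=self.cell_meta,
            provenance=dict(self.provenance),
        )


class GeneAnnotation:
    """Genomic positions per gene with a stable canonical order.

    Coordinates are 1-based inclusive (GTF convention). The canonical
    order — the order copy-number smoothing walks the genome in — sorts
    by (chromosome, start, gene_id); chromosomes sort as plain strings,
    so ``chr1 < chr10 < chr2`` (documented, deterministic). An optional
    ``arm`` column (e.g. ``1p``) supports arm-level summaries.
    """

    REQUIRED = ("gene_id", "chromosome", "start", "end")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise FormatError(f"gene annotation missing columns: {missing}")
        table = table.copy()
        table["start"] = table["start"].astype(int)
        table["end"] = table["end"].astype(int)
        if (table["start"] < 1).any() or (table["end"] < 1).any():
            raise FormatError("coordinates are 1-based; found value < 1")
        bad = table["start"] > table["end"]
        if bad.any():
            raise FormatError(
                f"start > end for genes: {table.loc[bad, 'gene_id'].tolist()[:5]}"
            )
        if table["gene_id"].duplicated().any():
            dups = table.loc[table["gene_id"].duplicated(), "gene_id"].tolist()
            raise FormatError(f"duplicated gene_id(s): {dups[:5]}")
        if "arm" not in table.columns:
            table["arm"] = pd.NA
        table = table.sort_values(
            ["chromosome", "start", "gene_id"], kind="mergesort"
        ).reset_index(drop=True)
        self.table = table

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gene_ids(self) -> np.ndarray:
        return self.table["gene_id"].to_numpy(dtype=object)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosomes in canonical (string-sorted) order."""
        return list(dict.fromkeys(self.table["chromosome"]))

    def ordered_genes(self, available: Sequence[str] | None = None) -> np.ndarray:
        """Gene ids in canonical genomic order, optionally restricted to
        an available set (order preserved)."""
        genes = self.gene_ids
        if available is not None:
            keep = set(available)
            genes = np.array([g for g in genes if g in keep], dtype=object)
        return genes

    def chromosome_of(self) -> pd.Series:
        return self.table.set_index("gene_id")["chromosome"]

    def arm_of(self) -> pd.Series:
        return self.table.set_index("gene_id")["arm"]
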