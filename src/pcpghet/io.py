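"""Readers and writers for the 10x-style counts directory layout.

On disk the matrix follows the 10x convention (genes x cells, Matrix
Market triplet, with ``features.tsv`` and ``barcodes.tsv`` sidecars and
an optional ``cells.tsv`` metadata table); in memory everything is
cells x genes. Gene positions are a 4+-column TSV with header
``gene_id  chromosome  start  end`` (coordinates 1-based inclusive) and
an optional ``arm`` column.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .data import CountMatrix, FormatError, GeneAnnotation

__all__ = [
    "read_counts_dir",
    "write_counts_dir",
    "read_gene_positions",
    "write_gene_positions",
]

MATRIX_FILE = "matrix.mtx"
FEATURES_FILE = "features.tsv"
BARCODES_FILE = "barcodes.tsv"
CELLS_FILE = "cells.tsv"
POSITION_COLUMNS = ["gene_id", "chromosome", "start", "end"]


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required file not found: {path}")
    return path


def _read_id_column(path: Path) -> pd.Series:
    """First column of a headerless TSV; empty file -> empty series."""
    try:
        return pd.read_csv(path, sep="\t", header=None)[0].astype(str)
    except pd.errors.EmptyDataError:
        return pd.Series([], dtype=str)


def read_counts_dir(path: str | os.PathLike) -> CountMatrix:
    """Load a counts directory into a :class:`CountMatrix`.

    The on-disk orientation (genes x cells) is transposed to cells x
    genes on load. Fractional entries in the triplet file are a hard
    format error: counts are integers by contract.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"counts directory not found: {path}")
    mat = scipy.io.mmread(_require(path / MATRIX_FILE))
    genes = _read_id_column(_require(path / FEATURES_FILE))
    barcodes = _read_id_column(_require(path / BARCODES_FILE))
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix shape {mat.shape} does not match sidecars "
            f"({len(genes)} features, {len(barcodes)} barcodes)"
        )
    data = np.asarray(sp.coo_matrix(mat).data)
    if data.size and not np.allclose(data, np.round(data)):
        raise FormatError(f"non-integer count in {path / MATRIX_FILE}")
    values = sp.csr_matrix(mat, dtype=np.int64).T.tocsr()

    meta = None
    cells_path = path / CELLS_FILE
    if cells_path.exists():
        meta = pd.read_csv(cells_path, sep="\t", dtype={"cell_id": str})
        if "cell_id" not in meta.columns:
            raise FormatError(f"{cells_path} lacks a cell_id column")
        if len(meta) != len(barcodes):
            raise FormatError(
                f"{cells_path} has {len(meta)} rows for {len(barcodes)} barcodes"
            )
        meta = meta.set_index("cell_id").reindex(barcodes)
        if meta.isna().all(axis=1).any():
            raise FormatError(f"{cells_path} barcodes do not match {BARCODES_FILE}")
        meta = meta.reset_index(drop=True)  # barcodes live in cell_ids
    return CountMatrix(
        values=values, cell_ids=barcodes.to_numpy(), gene_ids=genes.to_numpy(),
        cell_meta=meta,
    )


def write_counts_dir(cm: CountMatrix, path: str | os.PathLike) -> Path:
    """Write ``cm`` as a 10x-style directory; lossless round-trip with
    :func:`read_counts_dir`."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(cm.values.T.astype(np.int64))
    scipy.io.mmwrite(str(path / MATRIX_FILE), mat, field="integer")
    pd.Series(cm.gene_ids).to_csv(
        path / FEATURES_FILE, sep="\t", header=False, index=False
    )
    pd.Series(cm.cell_ids).to_csv(
        path / BARCODES_FILE, sep="\t", header=False, index=False
    )
    if len(cm.cell_meta.columns):
        meta = cm.cell_meta.copy()
        meta.insert(0, "cell_id", cm.cell_ids)
        meta.to_csv(path / CELLS_FILE, sep="\t", index=False)
    return path


def read_gene_positions(path: str | os.PathLike) -> GeneAnnotation:
    """Read a gene-position TSV into a :class:`GeneAnnotation`.

    Coordinates are 1-based inclusive. Rows are returned in canonical
    (chromosome, start, gene_id) order regardless of input order;
    duplicate gene ids and start > end are format errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene position table not found: {path}")
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in POSITION_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path} missing columns: {missing}")
    return GeneAnnotation(table)


def write_gene_positions(ann: GeneAnnotation, path: str | os.PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table = ann.table
    if table["arm"].isna().all():
        table = table[POSITION_COLUMNS]
    ann_cols = POSITION_COLUMNS + (["arm"] if "arm" in table.columns else [])
    table[ann_cols].to_csv(path, sep="\t", index=False)
    return path
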