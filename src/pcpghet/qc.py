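"""Cell filtering, log-normalization, variable-gene selection, scaling.

The cell filter follows the study design: within each library (sample),
cells whose number of detected genes falls below 10% or above 250% of
that library's mean are removed. The mean is computed once, on the
unfiltered library — re-running the filter recomputes the mean on the
surviving cells and may remove more; the filter is deliberately a
single pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import CountMatrix, NormalizedMatrix

__all__ = ["QCParams", "HVGSelection", "filter_cells", "normalize_log",
           "select_hvg", "scale_genes"]


@dataclass(frozen=True)
class QCParams:
    """Bounds on detected genes per cell, as fractions of the per-library
    mean (defaults 0.10 and 2.50)."""

    low_frac: float = 0.10
    high_frac: float = 2.50

    def __post_init__(self) -> None:
        if not (0 <= self.low_frac < self.high_frac):
            raise ValueError(
                f"require 0 <= low_frac < high_frac, got {self.low_frac}, {self.high_frac}"
            )


@dataclass
class HVGSelection:
    """Top variable genes sorted by dispersion statistic, descending."""

    genes: np.ndarray
    dispersion: np.ndarray  # statistic aligned to `genes`


def filter_cells(cm: CountMatrix, params: QCParams = QCParams()) -> CountMatrix:
    """Per-library detected-gene filter.

    For each library, compute the mean number of detected genes m on the
    unfiltered cells and retain cells with
    ``low_frac * m <= detected <= high_frac * m``. Libraries are
    independent: filtering a merged cohort equals filtering each library
    alone.
    """
    if "sample_id" not in cm.cell_meta.columns:
        raise ValueError("cell_meta lacks a sample_id column")
    samples = cm.cell_meta["sample_id"]
    if samples.isna().any():
        bad = cm.cell_ids[samples.isna().to_numpy()][:3]
        raise ValueError(f"cells with unknown sample_id: {list(bad)}")
    detected = cm.detected_genes_per_cell()
    keep = np.zeros(cm.n_cells, dtype=bool)
    for sample in samples.unique():
        mask = (samples == sample).to_numpy()
        m = detected[mask].mean()
        keep[mask] = (detected[mask] >= params.low_frac * m) & (
            detected[mask] <= params.high_frac * m
        )
    return cm.subset_cells(keep)


def normalize_log(cm: CountMatrix, scale_total: float = 10_000) -> NormalizedMatrix:
    """``ln(1 + count / cell_total * scale_total)`` per entry.

    Row-local: a cell's normalized vector depends only on its own counts,
    so it is invariant to rescaling all of the cell's counts.
    """
    totals = np.asarray(cm.values.sum(axis=1)).ravel().astype(float)
    zero = totals == 0
    if zero.any():
        raise ValueError(
            f"cells with zero total count: {list(cm.cell_ids[zero][:3])}"
        )
    x = cm.values.multiply(scale_total / totals[:, None]).tocsr()
    x.data = np.log1p(x.data)
    return NormalizedMatrix(
        values=np.asarray(x.todense()),
        cell_ids=cm.cell_ids,
        gene_ids=cm.gene_ids,
        cell_meta=cm.cell_meta,
        provenance={"scale_total": scale_total, "pseudocount": 1.0, "log_base": "e"},
    )


def select_hvg(nm: NormalizedMatrix, n: int = 4000, n_bins: int = 20) -> HVGSelection:
    """Rank genes by mean-standardized dispersion of log-normalized values.

    The dispersion statistic is the per-gene variance, z-standardized
    within ``n_bins`` equal-frequency bins of mean expression; this
    removes the mean-variance trend so highly variable genes are
    variable *for their expression level*.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if n > nm.n_genes:
        raise ValueError(f"n={n} exceeds number of genes ({nm.n_genes})")
    x = nm.values
    means = x.mean(axis=0)
    variances = x.var(axis=0)  # population variance

    order = np.argsort(means, kind="mergesort")
    bins = np.array_split(order, n_bins)
    z = np.zeros(nm.n_genes)
    for b in bins:
        v = variances[b]
        sd = v.std()
        z[b] = (v - v.mean()) / sd if sd > 0 else 0.0
    # constant genes carry no information regardless of their bin
    constant = x.max(axis=0) == x.min(axis=0)
    z[constant] = -np.inf

    rank = np.lexsort((nm.gene_ids, -z))[:n]
    stat = np.where(np.isneginf(z), 0.0, z)
    return HVGSelection(genes=nm.gene_ids[rank], dispersion=stat[rank])


def scale_genes(
    nm: NormalizedMatrix, genes, clip: float = 10.0
) -> np.ndarray:
    """Z-score the given genes across cells (population sd; zero-sd genes
    map to 0) and clip to ``[-clip, clip]``. Returns cells x len(genes)."""
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene list")
    idx = nm.gene_index(genes)
    x = nm.values[:, idx]
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    constant = x.max(axis=0) == x.min(axis=0)
    sd_safe = np.where(~constant & (sd > 0), sd, 1.0)
    z = (x - mu) / sd_safe
    z[:, constant] = 0.0
    return np.clip(z, -clip, clip)
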