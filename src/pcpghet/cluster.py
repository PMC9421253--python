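"""PCA, shared-nearest-neighbor graph clustering, marker detection and
marker-panel cell-type annotation.

Defaults follow the study design: 15 principal components on the scaled
variable genes, SNN graph with 20 neighbors and Jaccard edge weights,
resolution-scaled modularity clustering at resolution 0.3, Wilcoxon
rank-sum marker detection with a 25% detection / 0.25 log-fold-change
prefilter and a final adjusted p < 0.05, |log2FC| > 1.2 report filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .data import NormalizedMatrix

__all__ = ["Embedding", "Clustering", "pca", "cluster_graph", "find_markers",
           "annotate_celltypes", "composition_summary"]


@dataclass
class Embedding:
    """PCA coordinates (cells x components, ordered by explained variance)
    with the gene loadings kept for reproducibility checks."""

    coords: np.ndarray
    explained_variance: np.ndarray
    components: np.ndarray  # n_components x n_features loadings

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]


@dataclass
class Clustering:
    """Per-cell integer labels, contiguous from 0, largest cluster first."""

    labels: np.ndarray
    resolution: float
    modularity: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)


def pca(scaled: np.ndarray, n_components: int = 15, seed: int = 0) -> Embedding:
    """Truncated PCA of the (already scaled) matrix.

    Deterministic given the seed; the sign of each component is fixed by
    making its largest-magnitude gene loading positive.
    """
    if n_components <= 0:
        raise ValueError(f"n_components must be positive, got {n_components}")
    if n_components > min(scaled.shape):
        raise ValueError(
            f"n_components={n_components} exceeds min(cells, genes)={min(scaled.shape)}"
        )
    solver = "full" if min(scaled.shape) < 500 else "randomized"
    model = PCA(n_components=n_components, svd_solver=solver, random_state=seed)
    coords = model.fit_transform(np.asarray(scaled, dtype=float))
    comps = model.components_
    flip = np.sign(comps[np.arange(comps.shape[0]), np.abs(comps).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return Embedding(
        coords=coords * flip[None, :],
        explained_variance=model.explained_variance_,
        components=comps * flip[:, None],
    )


def snn_graph(
    coords: np.ndarray, k_neighbors: int = 20, prune: float = 1 / 15
) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph on Euclidean distances.

    Each cell keeps its ``k_neighbors`` nearest cells (self included in
    the neighbor set); edge weight is the Jaccard overlap of the two
    neighbor sets, pruned below ``prune``.
    """
    n = coords.shape[0]
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n_cells={n}")
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(coords)
    idx = nn.kneighbors(return_distance=False)  # excludes self
    rows = np.repeat(np.arange(n), k_neighbors + 1)
    cols = np.concatenate([idx, np.arange(n)[:, None]], axis=1).ravel()
    a = sp.csr_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n, n), dtype=float
    )
    shared = (a @ a.T).tocoo()
    size = k_neighbors + 1
    jaccard = shared.data / (2 * size - shared.data)
    keep = (jaccard >= prune) & (shared.row != shared.col)
    return sp.csr_matrix(
        (jaccard[keep], (shared.row[keep], shared.col[keep])), shape=(n, n)
    )


def cluster_graph(
    embedding: Embedding,
    k_neighbors: int = 20,
    resolution: float = 0.3,
    seed: int = 0,
) -> Clustering:
    """Partition the SNN graph by maximizing resolution-scaled modularity
    (Louvain-style local moving with refinement). Deterministic given the
    seed; labels are renumbered largest-cluster-first."""
    n = embedding.coords.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 cells, got {n}")
    adj = snn_graph(embedding.coords, k_neighbors=k_neighbors)
    sources, targets = adj.nonzero()
    upper = sources < targets
    g = ig.Graph(
        n=n,
        edges=list(zip(sources[upper].tolist(), targets[upper].tolist())),
        edge_attrs={"weight": np.asarray(adj[sources[upper], targets[upper]]).ravel().tolist()},
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,  # iterate until the objective stops improving
    )
    raw = np.asarray(part.membership)
    sizes = np.bincount(raw)
    order = np.lexsort((np.arange(sizes.size), -sizes))
    remap = np.empty_like(order)
    remap[order] = np.arange(order.size)
    return Clustering(
        labels=remap[raw], resolution=resolution, modularity=float(part.quality())
    )


def modularity(adj: sp.spmatrix, labels: np.ndarray, resolution: float) -> float:
    """Resolution-scaled Newman modularity of a partition on a weighted
    graph — the objective cluster_graph maximizes; exposed for tests."""
    adj = sp.csr_matrix(adj)
    m2 = adj.sum()
    if m2 == 0:
        return 0.0
    deg = np.asarray(adj.sum(axis=1)).ravel()
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        within = adj[mask][:, mask].sum()
        q += within / m2 - resolution * (deg[mask].sum() / m2) ** 2
    return float(q)


def find_markers(
    nm: NormalizedMatrix,
    clustering: Clustering,
    min_pct: float = 0.25,
    min_logfc: float = 0.25,
    max_adj_p: float = 0.05,
    min_log2fc: float = 1.2,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker detection with the two-stage filter.

    Genes detected in >= ``min_pct`` of the cluster's cells and with
    |natural-log fold change| >= ``min_logfc`` are tested (rank-sum,
    exact for tiny tie-free groups, tie-corrected normal approximation
    otherwise), Bonferroni-adjusted over all genes in the matrix, and
    the report keeps rows with adjusted p < ``max_adj_p`` and
    |log2FC| > ``min_log2fc``. Fold changes are computed on mean
    expm1-normalized expression with a pseudocount of 1.
    """
    if clustering.n_clusters < 2:
        raise ValueError("marker detection needs at least 2 clusters")
    x = nm.values
    rows = []
    for c in range(clustering.n_clusters):
        mask = clustering.labels == c
        n_in = int(mask.sum())
        if n_in < 3:
            warnings.warn(f"cluster {c} has {n_in} cells; skipped")
            continue
        x_in, x_out = x[mask], x[~mask]
        pct_in = (x_in > 0).mean(axis=0)
        pct_out = (x_out > 0).mean(axis=0)
        mean_in = np.expm1(x_in).mean(axis=0)
        mean_out = np.expm1(x_out).mean(axis=0)
        logfc = np.log(mean_in + 1.0) - np.log(mean_out + 1.0)
        test = (pct_in >= min_pct) & (np.abs(logfc) >= min_logfc)
        if not test.any():
            continue
        res = stats.mannwhitneyu(
            x_in[:, test], x_out[:, test], alternative="two-sided",
            axis=0, method="auto",
        )
        pvals = np.atleast_1d(res.pvalue)
        adj = np.minimum(pvals * nm.n_genes, 1.0)
        log2fc = logfc[test] / np.log(2.0)
        keep = (adj < max_adj_p) & (np.abs(log2fc) > min_log2fc)
        for gi, p, ap, l2 in zip(
            np.flatnonzero(test)[keep], pvals[keep], adj[keep], log2fc[keep]
        ):
            rows.append(
                {
                    "cluster": c, "gene": nm.gene_ids[gi],
                    "log2_fold_change": l2,
                    "pct_in": pct_in[gi], "pct_out": pct_out[gi],
                    "p_value": p, "adjusted_p": ap,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["cluster", "gene", "log2_fold_change", "pct_in", "pct_out",
                 "p_value", "adjusted_p"],
    )
    return table.sort_values(
        ["cluster", "p_value", "gene"], kind="mergesort"
    ).reset_index(drop=True)


def annotate_celltypes(
    nm: NormalizedMatrix, clustering: Clustering, panels: dict
) -> pd.DataFrame:
    """Assign each cluster the marker panel with the highest mean
    normalized expression.

    Returns one row per cluster with the winning ``cell_type``, the
    score ``margin`` to the runner-up, and an ``ambiguous`` flag for
    exact ties (broken by panel order).
    """
    panel_scores = {}
    for ctype, genes in panels.items():
        if not genes:
            raise ValueError(f"panel {ctype!r} is empty")
        present = [g for g in genes if g in set(nm.gene_ids)]
        missing = sorted(set(genes) - set(present))
        if missing:
            warnings.warn(f"panel {ctype!r}: dropping missing genes {missing}")
        if not present:
            raise ValueError(f"panel {ctype!r}: no panel gene present in matrix")
        panel_scores[ctype] = nm.values[:, nm.gene_index(present)].mean(axis=1)

    types = list(panels)
    rows = []
    for c in range(clustering.n_clusters):
        mask = clustering.labels == c
        means = np.array([panel_scores[t][mask].mean() for t in types])
        order = np.argsort(-means, kind="mergesort")  # ties -> panel order
        best, second = order[0], order[1] if len(order) > 1 else order[0]
        rows.append(
            {
                "cluster": c,
                "cell_type": types[best],
                "margin": float(means[best] - means[second]),
                "ambiguous": bool(means[best] == means[second] and len(order) > 1),
            }
        )
    return pd.DataFrame(rows)


def cell_type_labels(clustering: Clustering, annotation: pd.DataFrame) -> np.ndarray:
    """Per-cell type labels from a per-cluster annotation table."""
    lut = annotation.set_index("cluster")["cell_type"]
    return lut.reindex(clustering.labels).to_numpy(dtype=object)


def composition_summary(
    cell_types: np.ndarray, cell_meta: pd.DataFrame
) -> pd.DataFrame:
    """Cell-type fractions overall and per sample.

    Returns tidy rows (scope, cell_type, n_cells, fraction) where scope
    is ``"overall"`` or a sample id; fractions sum to 1 per scope.
    """
    df = pd.DataFrame(
        {"cell_type": cell_types, "sample_id": cell_meta["sample_id"].to_numpy()}
    )
    out = []
    scopes = [("overall", df)] + [
        (s, grp) for s, grp in df.groupby("sample_id", sort=True)
    ]
    for scope, grp in scopes:
        counts = grp["cell_type"].value_counts()
        for ctype, n in counts.sort_index().items():
            out.append(
                {"scope": scope, "cell_type": ctype, "n_cells": int(n),
                 "fraction": n / len(grp)}
            )
    return pd.DataFrame(out)
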