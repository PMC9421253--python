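"""Per-sample NMF programs and cohort-wide metaprograms.

This is the analytical core: for each tumor sample, non-negative matrix
factorization (multiplicative updates, k factors) of the log-normalized
tumor-cell x variable-gene submatrix extracts transcriptional programs;
each factor is reduced to its top-50 genes by loading. All tumor cells
in the cohort are then scored for every program with a binned-control
module score, programs are hierarchically clustered on the Pearson
correlation of their cell-score profiles (distance 1 - r, Ward linkage),
and each resulting metaprogram is summarized by its genes ranked by
frequency of presence among the constituent programs. Metaprogram
scores are finally compared between mutation groups with a Wilcoxon
rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .data import NormalizedMatrix

__all__ = ["NMFResult", "Program", "ProgramSet", "MetaprogramSet",
           "prepare_nmf_input", "nmf_factorize", "extract_programs",
           "module_score", "score_all_programs", "cluster_metaprograms",
           "score_metaprograms", "compare_groups"]

_EPS = 1e-10


# ---------------------------------------------------------------------
# NMF
# ---------------------------------------------------------------------

@dataclass
class NMFResult:
    sample_id: str
    W: np.ndarray  # genes x k, columns unit L2
    H: np.ndarray  # k x cells
    k: int
    objective: np.ndarray  # Frobenius loss per iteration, non-increasing
    seed: int
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.H


def prepare_nmf_input(
    nm_sample: NormalizedMatrix, baseline_shift: bool = True
) -> NormalizedMatrix:
    """NMF input transform for one sample's tumor-cell submatrix.

    With ``baseline_shift`` (the default), each gene's per-sample minimum
    is subtracted so the ubiquitous baseline component — which every cell
    expresses and which would otherwise consume factors shared across
    all samples — is removed while non-negativity is preserved. With
    ``baseline_shift=False`` the log-normalized values are factorized
    as-is (the documented alternative input convention).
    """
    x = np.asarray(nm_sample.values, dtype=float)
    if baseline_shift:
        x = x - x.min(axis=0, keepdims=True)
    return NormalizedMatrix(
        values=x, cell_ids=nm_sample.cell_ids, gene_ids=nm_sample.gene_ids,
        cell_meta=nm_sample.cell_meta,
        provenance={**nm_sample.provenance, "baseline_shift": baseline_shift},
    )


def nmf_factorize(
    nm_sample: NormalizedMatrix,
    k: int = 28,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
    sample_id: str | None = None,
) -> NMFResult:
    """Factorize X (genes x cells) = W H by multiplicative updates.

    Initialization is seeded uniform-random scaled by ``sqrt(mean(X)/k)``;
    iteration stops when the relative change of the Frobenius loss falls
    below ``tol`` or at ``max_iter``. The loss is non-increasing at every
    update (the multiplicative-update guarantee); W columns are rescaled
    to unit L2 with compensation in H on exit.
    """
    x = np.asarray(nm_sample.values, dtype=float).T  # genes x cells
    n_genes, n_cells = x.shape
    if k >= min(n_genes, n_cells):
        raise ValueError(f"k={k} must be < min(genes, cells)={min(x.shape)}")
    if not np.any(x > 0):
        raise ValueError("all-zero matrix cannot be factorized")
    if np.any(x < 0):
        raise ValueError("NMF input must be non-negative")

    rng = np.random.default_rng(seed)
    scale = np.sqrt(x.mean() / k)
    w = rng.random((n_genes, k)) * scale + _EPS
    h = rng.random((k, n_cells)) * scale + _EPS

    x_sq = float((x * x).sum())
    trace = []
    prev = None
    for _ in range(max_iter):
        h *= (w.T @ x) / (w.T @ w @ h + _EPS)
        xht = x @ h.T
        hht = h @ h.T
        w *= xht / (w @ hht + _EPS)
        # ||X - WH||^2 expanded; reuses the update's cross products
        loss_sq = x_sq - 2.0 * float((w * xht).sum()) + float(((w.T @ w) * hht).sum())
        loss = np.sqrt(max(loss_sq, 0.0))
        trace.append(loss)
        if prev is not None and prev > 0 and (prev - loss) / prev < tol:
            break
        prev = loss

    norms = np.linalg.norm(w, axis=0)
    norms[norms == 0] = 1.0
    w = w / norms[None, :]
    h = h * norms[:, None]
    return NMFResult(
        sample_id=sample_id or str(nm_sample.cell_meta.get("sample_id", pd.Series(["?"])).iloc[0]),
        W=w, H=h, k=k, objective=np.asarray(trace), seed=seed,
        gene_ids=nm_sample.gene_ids, cell_ids=nm_sample.cell_ids,
    )


# ---------------------------------------------------------------------
# programs
# ---------------------------------------------------------------------

@dataclass
class Program:
    sample_id: str
    factor_index: int
    genes: list
    loadings: np.ndarray  # descending, aligned to genes

    @property
    def label(self) -> str:
        return f"{self.sample_id}|f{self.factor_index}"


@dataclass
class ProgramSet:
    programs: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.programs)

    def labels(self) -> list:
        return [p.label for p in self.programs]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_id": p.sample_id, "factor": p.factor_index, "rank": r,
             "gene": g, "loading": l}
            for p in self.programs
            for r, (g, l) in enumerate(zip(p.genes, p.loadings), start=1)
        ]
        return pd.DataFrame(rows)


def extract_programs(result: NMFResult, top_n: int = 50) -> ProgramSet:
    """Top ``top_n`` genes per factor by W loading (descending, ties by
    gene id). Factors with fewer than ``top_n`` strictly positive
    loadings yield shorter programs, with a warning."""
    programs = []
    for f in range(result.k):
        loadings = result.W[:, f]
        order = np.lexsort((result.gene_ids, -loadings))
        order = order[loadings[order] > 0][:top_n]
        if len(order) < top_n:
            warnings.warn(
                f"factor {f} of {result.sample_id}: only {len(order)} "
                f"positive loadings (< {top_n})"
            )
        programs.append(
            Program(
                sample_id=result.sample_id, factor_index=f,
                genes=list(result.gene_ids[order]),
                loadings=loadings[order].copy(),
            )
        )
    return ProgramSet(programs)


# ---------------------------------------------------------------------
# module scoring
# ---------------------------------------------------------------------

def _expression_bins(values: np.ndarray, n_bins: int) -> list[np.ndarray]:
    """Equal-frequency bins of gene indices by mean expression."""
    order = np.argsort(values.mean(axis=0), kind="mergesort")
    return [b for b in np.array_split(order, n_bins) if b.size]


def module_score(
    nm: NormalizedMatrix,
    gene_set,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
    _bins: list | None = None,
) -> np.ndarray:
    """Binned-control gene-set score per cell.

    All genes are binned into ``n_bins`` equal-frequency bins by mean
    expression; each gene-set gene contributes ``n_ctrl`` control genes
    sampled (with replacement, seeded) from its bin. The score is the
    mean expression of the gene set minus the mean expression of the
    pooled controls, so an uninformative set scores ~0 regardless of its
    expression level.
    """
    present = [g for g in gene_set if g in set(nm.gene_ids)]
    if not present:
        raise ValueError("gene set has no genes in the matrix")
    x = nm.values
    bins = _bins if _bins is not None else _expression_bins(x, n_bins)
    bin_of = np.empty(x.shape[1], dtype=int)
    for bi, b in enumerate(bins):
        bin_of[b] = bi
    rng = np.random.default_rng(seed)
    set_idx = nm.gene_index(present)
    ctrl_weight = np.zeros(x.shape[1])
    for gi in set_idx:
        picks = rng.choice(bins[bin_of[gi]], size=n_ctrl, replace=True)
        np.add.at(ctrl_weight, picks, 1.0)
    ctrl_weight /= ctrl_weight.sum()
    return x[:, set_idx].mean(axis=1) - x @ ctrl_weight


def score_all_programs(
    nm_tumor: NormalizedMatrix,
    programs: ProgramSet,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every cell for every program (columns in program order).

    Binning is computed once and shared; each program draws its control
    genes from a seed derived as ``seed + program index``, so adding a
    program never changes existing columns.
    """
    if len(programs) == 0:
        raise ValueError("no programs to score")
    bins = _expression_bins(nm_tumor.values, n_bins)
    cols = {}
    for i, prog in enumerate(programs.programs):
        cols[prog.label] = module_score(
            nm_tumor, prog.genes, n_bins=n_bins, n_ctrl=n_ctrl,
            seed=seed + i, _bins=bins,
        )
    return pd.DataFrame(cols, index=nm_tumor.cell_ids)


# ---------------------------------------------------------------------
# metaprograms
# ---------------------------------------------------------------------

@dataclass
class MetaprogramSet:
    """Clustering of programs into metaprograms M1..Mn with
    frequency-ranked gene lists."""

    assignment: pd.Series  # program label -> metaprogram id (1-based int)
    n_meta: int
    gene_tables: dict  # metaprogram id -> DataFrame(gene, frequency, mean_rank)
    linkage_matrix: np.ndarray
    silhouette_by_k: dict

    def top_genes(self, meta_id: int, top_n: int = 50) -> list:
        return list(self.gene_tables[meta_id]["gene"].head(top_n))

    def genes_frame(self) -> pd.DataFrame:
        frames = []
        for mid, tab in self.gene_tables.items():
            t = tab.copy()
            t.insert(0, "metaprogram", f"M{mid}")
            frames.append(t)
        return pd.concat(frames, ignore_index=True)


def _rank_genes(members: list) -> pd.DataFrame:
    """Frequency-ranked union of member programs' genes; frequency is the
    fraction of member programs containing the gene, ties broken by mean
    within-program loading rank (then gene id)."""
    count: dict = {}
    ranksum: dict = {}
    for prog in members:
        for r, g in enumerate(prog.genes, start=1):
            count[g] = count.get(g, 0) + 1
            ranksum[g] = ranksum.get(g, 0) + r
    tab = pd.DataFrame(
        {
            "gene": list(count),
            "frequency": [count[g] / len(members) for g in count],
            "mean_rank": [ranksum[g] / count[g] for g in count],
        }
    )
    return tab.sort_values(
        ["frequency", "mean_rank", "gene"], ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)


def cluster_metaprograms(
    score_matrix: pd.DataFrame,
    programs: ProgramSet,
    n_meta: int | str = "auto",
    k_range: tuple = (2, 15),
    min_sd_frac: float = 0.5,
) -> MetaprogramSet:
    """Pearson/Ward clustering of program score profiles.

    Distance between programs is 1 - Pearson r of their per-cell score
    columns; the Ward dendrogram is cut either at ``n_meta`` clusters or,
    for ``"auto"``, at the K in ``k_range`` maximizing the mean
    silhouette on the precomputed distances (ties -> smallest K).
    Programs with (near-)constant score columns — sd below
    ``min_sd_frac`` times the median column sd — discriminate no cell
    state and are dropped with a warning before clustering.
    """
    if len(programs) < 2:
        raise ValueError("need at least 2 programs to cluster")
    x = score_matrix.to_numpy(dtype=float)
    sds = x.std(axis=0)
    keep = (sds > 0) & (sds >= min_sd_frac * np.median(sds))
    if keep.sum() < 2:
        raise ValueError("fewer than 2 programs with non-degenerate scores")
    if not keep.all():
        dropped = list(score_matrix.columns[~keep])
        warnings.warn(
            f"dropping {len(dropped)} (near-)constant score columns: {dropped[:5]}..."
        )
    labels_kept = list(score_matrix.columns[keep])
    progs_by_label = {p.label: p for p in programs.programs}
    corr = np.corrcoef(x[:, keep], rowvar=False)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    z = linkage(squareform(dist, checks=False), method="ward")

    sil: dict = {}
    if n_meta == "auto":
        best_k, best_s = None, -np.inf
        lo, hi = k_range
        for k in range(lo, min(hi, len(labels_kept) - 1) + 1):
            lab = fcluster(z, t=k, criterion="maxclust")
            if len(np.unique(lab)) < 2:
                continue
            s = silhouette_score(dist, lab, metric="precomputed")
            sil[k] = float(s)
            if s > best_s + 1e-12:
                best_k, best_s = k, s
        if best_k is None:
            raise ValueError("auto cut failed: no K produced >= 2 clusters")
        k_cut = best_k
    else:
        k_cut = int(n_meta)
    raw = fcluster(z, t=k_cut, criterion="maxclust")

    # renumber metaprograms by size (largest = M1), ties by first occurrence
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], list(raw).index(c)))
    remap = {old: new for new, old in enumerate(order, start=1)}
    labels = np.array([remap[c] for c in raw])

    assignment = pd.Series(labels, index=labels_kept, name="metaprogram")
    gene_tables = {
        mid: _rank_genes(
            [progs_by_label[l] for l in assignment.index[assignment == mid]]
        )
        for mid in range(1, len(order) + 1)
    }
    return MetaprogramSet(
        assignment=assignment,
        n_meta=len(order),
        gene_tables=gene_tables,
        linkage_matrix=z,
        silhouette_by_k=sil,
    )


def score_metaprograms(
    nm_tumor: NormalizedMatrix,
    metaprograms: MetaprogramSet,
    top_n_genes: int = 50,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Module score of each metaprogram's top frequency-ranked genes,
    per cell. Columns M1..Mn."""
    bins = _expression_bins(nm_tumor.values, n_bins)
    cols = {}
    for mid in sorted(metaprograms.gene_tables):
        genes = metaprograms.top_genes(mid, top_n=top_n_genes)
        cols[f"M{mid}"] = module_score(
            nm_tumor, genes, n_bins=n_bins, n_ctrl=n_ctrl,
            seed=seed + mid, _bins=bins,
        )
    return pd.DataFrame(cols, index=nm_tumor.cell_ids)


def compare_groups(
    meta_scores: pd.DataFrame, mutation_group: np.ndarray
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum of per-cell metaprogram scores between
    the two mutation groups, with group means."""
    groups = pd.unique(np.asarray(mutation_group, dtype=object))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(groups)}")
    g1, g2 = sorted(groups)
    m1 = np.asarray(mutation_group, dtype=object) == g1
    if m1.sum() < 3 or (~m1).sum() < 3:
        raise ValueError("each group needs at least 3 cells")
    rows = []
    for col in meta_scores.columns:
        a = meta_scores.loc[m1, col].to_numpy()
        b = meta_scores.loc[~m1, col].to_numpy()
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
        rows.append(
            {
                "metaprogram": col,
                f"mean_{g1}": a.mean(), f"mean_{g2}": b.mean(),
                "statistic": float(res.statistic), "p_value": float(res.pvalue),
            }
        )
    return pd.DataFrame(rows)
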