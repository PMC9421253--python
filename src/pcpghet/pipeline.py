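"""End-to-end orchestration: one config, one master seed, one output tree.

Stage order follows the analysis design: simulate (or load) -> QC filter
-> normalize -> variable genes -> scale -> PCA -> graph clustering ->
markers -> cell-type annotation -> composition -> tumor-cell selection
(annotated neuroendocrine cells, excluded samples dropped) -> inferred
CNV -> per-sample NMF programs -> cohort program scoring -> metaprogram
clustering and scoring -> mutation-group comparison -> reference
similarity. Every stochastic choice draws its seed from the master seed,
and each stage's outputs are hashed into a run manifest so determinism
is checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import cnv as cnvmod
from . import metaprograms as mp
from . import qc as qcmod
from . import similarity as sim
from .data import CountMatrix, GeneAnnotation
from .io import read_counts_dir, read_gene_positions, write_counts_dir, write_gene_positions
from .simulate import DEFAULT_MARKER_PANELS, default_config, generate_cohort

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "make_fixtures"]

log = logging.getLogger("pcpghet")

TUMOR_TYPE = "neuroendocrine"
FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """All stage parameters, with the study's values as defaults.

    ``counts_dir``/``gene_positions`` select real input; when both are
    None a synthetic cohort is generated from :func:`default_config`
    (size overrides via ``synthetic``).
    """

    counts_dir: str | None = None
    gene_positions: str | None = None
    synthetic: dict = field(default_factory=dict)  # CohortConfig overrides
    excluded_samples: list | None = None  # None -> generator's own exclusion

    # QC / normalization
    low_frac: float = 0.10
    high_frac: float = 2.50
    scale_total: float = 10_000
    n_hvg: int = 4000
    scale_clip: float = 10.0

    # clustering / markers / annotation
    n_pcs: int = 15
    k_neighbors: int = 20
    resolution: float = 0.3
    min_pct: float = 0.25
    min_logfc: float = 0.25
    marker_max_adj_p: float = 0.05
    marker_min_log2fc: float = 1.2
    marker_panels: dict = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_MARKER_PANELS.items()}
    )

    # CNV
    cnv_window: int = 101
    cnv_clamp: float = 3.0
    cnv_delta: float = 0.15
    cnv_p_stay: float = 0.99
    cnv_denoise_sigma: float = 1.5

    # NMF / metaprograms
    nmf_baseline_shift: bool = True
    nmf_k: int = 28
    nmf_max_iter: int = 500
    nmf_tol: float = 1e-5
    top_n_genes: int = 50
    n_meta: object = "auto"
    score_bins: int = 25
    score_ctrl: int = 100

    # similarity
    similarity_enabled: bool = True
    similarity_alpha: float = 0.6
    similarity_folds: int = 5
    similarity_holdout: float = 0.2
    similarity_max_ref_per_type: int = 100
    similarity_n_genes: int = 600

    seed: int = 0
    outdir: str = "pcpghet_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not (0 <= self.low_frac < self.high_frac):
            raise ValueError("require 0 <= low_frac < high_frac")
        if self.n_meta != "auto":
            if not isinstance(self.n_meta, int) or self.n_meta < 2:
                raise ValueError(f"n_meta must be 'auto' or an int >= 2, got {self.n_meta!r}")
        qcmod.QCParams(self.low_frac, self.high_frac)
        cnvmod.CNVParams(self.cnv_window, self.cnv_clamp, self.cnv_delta,
                         self.cnv_p_stay)


@dataclass
class RunManifest:
    config: dict
    stages: list = field(default_factory=list)
    hashes: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)

    def record(self, name: str, seconds: float, outputs: list) -> None:
        files = {}
        for p in outputs:
            p = Path(p)
            files[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
        self.stages.append({"stage": name, "seconds": round(seconds, 3),
                            "outputs": sorted(files)})
        self.hashes.update(files)

    def write(self, path: Path) -> None:
        payload = {"config": self.config, "stages": self.stages,
                   "hashes": dict(sorted(self.hashes.items())),
                   "seeds": self.seeds}
        path.write_text(json.dumps(payload, indent=2, sort_keys=False))


def synthetic_pipeline_config(seed: int, outdir) -> PipelineConfig:
    """Pipeline configuration for the default synthetic cohort.

    Stage parameters keep their study defaults; only the size-dependent
    variable-gene count is scaled to the miniature 2000-gene genome
    (1200 variable genes, ~60% of the genome, mirroring the 4000-of-
    many-thousand proportion used at full scale)."""
    return PipelineConfig(n_hvg=1200, seed=seed, outdir=str(outdir))


def _stage_seeds(master: int) -> dict:
    """One derived seed per stochastic stage, all below 2**31."""
    ss = np.random.SeedSequence(master)
    names = ["cohort", "pca", "graph", "scoring", "similarity", "holdout"]
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages, writing TSV artifacts and a manifest under
    ``config.outdir``. Returns the manifest; identical config and seed
    reproduce identical output hashes."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest = RunManifest(config=_config_dict(config), seeds=seeds)

    def stage(name):
        log.info("stage %s", name)
        return time.perf_counter()

    # ---- input ------------------------------------------------------
    t0 = stage("input")
    if config.counts_dir is not None:
        cm = read_counts_dir(config.counts_dir)
        ann = read_gene_positions(config.gene_positions)
        excluded = list(config.excluded_samples or [])
        outputs = []
    else:
        cohort_cfg = default_config(seed=seeds["cohort"])
        for key, val in config.synthetic.items():
            if not hasattr(cohort_cfg, key):
                raise ValueError(f"unknown synthetic config key: {key}")
            setattr(cohort_cfg, key, val)
        cm, ann, truth = generate_cohort(cohort_cfg)
        excluded = list(
            config.excluded_samples
            if config.excluded_samples is not None
            else cohort_cfg.excluded_samples
        )
        truth.write(outdir / "truth")
        write_gene_positions(ann, outdir / "gene_positions.tsv")
        outputs = [outdir / "gene_positions.tsv"]
    manifest.record("input", time.perf_counter() - t0, outputs)

    # ---- QC + normalization -----------------------------------------
    t0 = stage("qc")
    filtered = qcmod.filter_cells(cm, qcmod.QCParams(config.low_frac, config.high_frac))
    qc_summary = pd.DataFrame(
        {
            "sample_id": cm.cell_meta["sample_id"].unique(),
        }
    )
    before = cm.cell_meta["sample_id"].value_counts()
    after = filtered.cell_meta["sample_id"].value_counts()
    qc_summary["cells_before"] = qc_summary["sample_id"].map(before).fillna(0).astype(int)
    qc_summary["cells_after"] = qc_summary["sample_id"].map(after).fillna(0).astype(int)
    qc_summary.to_csv(outdir / "qc_summary.tsv", sep="\t", index=False)
    nm = qcmod.normalize_log(filtered, scale_total=config.scale_total)
    n_hvg = min(config.n_hvg, nm.n_genes)
    hvg = qcmod.select_hvg(nm, n=n_hvg)
    pd.DataFrame({"gene": hvg.genes, "dispersion": hvg.dispersion}).to_csv(
        outdir / "hvg.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )
    manifest.record("qc", time.perf_counter() - t0,
                    [outdir / "qc_summary.tsv", outdir / "hvg.tsv"])

    # ---- clustering + annotation ------------------------------------
    t0 = stage("cluster")
    scaled = qcmod.scale_genes(nm, hvg.genes, clip=config.scale_clip)
    emb = cl.pca(scaled, n_components=config.n_pcs, seed=seeds["pca"])
    clustering = cl.cluster_graph(
        emb, k_neighbors=config.k_neighbors, resolution=config.resolution,
        seed=seeds["graph"],
    )
    markers = cl.find_markers(
        nm, clustering, min_pct=config.min_pct, min_logfc=config.min_logfc,
        max_adj_p=config.marker_max_adj_p, min_log2fc=config.marker_min_log2fc,
    )
    annotation = cl.annotate_celltypes(nm, clustering, config.marker_panels)
    cell_types = cl.cell_type_labels(clustering, annotation)
    composition = cl.composition_summary(cell_types, nm.cell_meta)
    pd.DataFrame(
        {"cell_id": nm.cell_ids, "cluster": clustering.labels, "cell_type": cell_types}
    ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    markers.to_csv(outdir / "markers.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    composition.to_csv(outdir / "composition.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    manifest.record(
        "cluster", time.perf_counter() - t0,
        [outdir / f for f in ["clusters.tsv", "markers.tsv", "annotation.tsv",
                              "composition.tsv"]],
    )

    # ---- tumor selection --------------------------------------------
    keep = ~nm.cell_meta["sample_id"].isin(excluded).to_numpy()
    nm_kept = nm.subset_cells(keep)
    types_kept = cell_types[keep]
    is_tumor = types_kept == TUMOR_TYPE
    samples_kept = nm_kept.cell_meta["sample_id"].to_numpy(dtype=object)
    analyzed_samples = sorted(pd.unique(samples_kept[is_tumor]))

    # ---- CNV ---------------------------------------------------------
    t0 = stage("cnv")
    group_labels = np.where(
        is_tumor,
        np.char.add("tumor:", samples_kept.astype(str)),
        np.char.add("ref:", types_kept.astype(str)),
    ).astype(object)
    reference_groups = set(g for g in pd.unique(group_labels) if g.startswith("ref:"))
    profile = cnvmod.infer_cnv(
        nm_kept, ann, group_labels, reference_groups,
        params=cnvmod.CNVParams(config.cnv_window, config.cnv_clamp,
                                config.cnv_delta, config.cnv_p_stay,
                                config.cnv_denoise_sigma),
    )
    profile.states_frame().rename_axis("group").reset_index().to_csv(
        outdir / "cnv_states.tsv", sep="\t", index=False
    )
    arm_tab = cnvmod.arm_summary(profile)
    arm_tab.to_csv(outdir / "cnv_arm_summary.tsv", sep="\t", index=False,
                   float_format=FLOAT_FMT)
    manifest.record("cnv", time.perf_counter() - t0,
                    [outdir / "cnv_states.tsv", outdir / "cnv_arm_summary.tsv"])

    # ---- per-sample NMF programs ------------------------------------
    t0 = stage("nmf")
    hvg_set = list(hvg.genes)
    nm_tumor = nm_kept.subset_cells(is_tumor).subset_genes(hvg_set)
    all_programs = mp.ProgramSet()
    for si, sample in enumerate(analyzed_samples):
        nm_s = mp.prepare_nmf_input(
            nm_tumor.subset_cells(
                nm_tumor.cell_meta["sample_id"].to_numpy() == sample
            ),
            baseline_shift=config.nmf_baseline_shift,
        )
        result = mp.nmf_factorize(
            nm_s, k=config.nmf_k, seed=seeds["cohort"] + 1000 + si,
            max_iter=config.nmf_max_iter, tol=config.nmf_tol, sample_id=sample,
        )
        all_programs.programs.extend(
            mp.extract_programs(result, top_n=config.top_n_genes).programs
        )
    all_programs.to_frame().to_csv(
        outdir / "programs.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )
    manifest.record("nmf", time.perf_counter() - t0, [outdir / "programs.tsv"])

    # ---- metaprograms -----------------------------------------------
    t0 = stage("metaprograms")
    scores = mp.score_all_programs(
        nm_tumor, all_programs, n_bins=config.score_bins,
        n_ctrl=config.score_ctrl, seed=seeds["scoring"],
    )
    metaset = mp.cluster_metaprograms(scores, all_programs, n_meta=config.n_meta)
    meta_scores = mp.score_metaprograms(
        nm_tumor, metaset, top_n_genes=config.top_n_genes,
        n_bins=config.score_bins, n_ctrl=config.score_ctrl,
        seed=seeds["scoring"] + 10_000,
    )
    comparison = mp.compare_groups(
        meta_scores, nm_tumor.cell_meta["mutation_group"].to_numpy(object)
    )
    metaset.assignment.rename_axis("program").reset_index().to_csv(
        outdir / "metaprogram_assignment.tsv", sep="\t", index=False
    )
    metaset.genes_frame().to_csv(
        outdir / "metaprogram_genes.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )
    meta_scores.rename_axis("cell_id").reset_index().to_csv(
        outdir / "metaprogram_scores.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )
    comparison.to_csv(outdir / "group_comparison.tsv", sep="\t", index=False,
                      float_format=FLOAT_FMT)
    manifest.record(
        "metaprograms", time.perf_counter() - t0,
        [outdir / f for f in ["metaprogram_assignment.tsv", "metaprogram_genes.tsv",
                              "metaprogram_scores.tsv", "group_comparison.tsv"]],
    )

    # ---- similarity --------------------------------------------------
    if config.similarity_enabled:
        t0 = stage("similarity")
        rng = np.random.default_rng(seeds["holdout"])
        n = nm_kept.n_cells
        holdout = np.zeros(n, dtype=bool)
        for t in pd.unique(types_kept):
            idx = np.flatnonzero(types_kept == t)
            k = max(10, int(round(config.similarity_holdout * len(idx))))
            k = min(k, config.similarity_max_ref_per_type, len(idx))
            holdout[rng.choice(idx, size=k, replace=False)] = True
        # top variable genes carry the type signal; a compact feature set
        # keeps the penalized fits fast
        nm_hvg = nm_kept.subset_genes(hvg_set[: config.similarity_n_genes])
        ref = sim.ReferenceSet(nm_hvg.subset_cells(holdout), types_kept[holdout])
        model = sim.train_similarity_model(
            ref, alpha=config.similarity_alpha, n_folds=config.similarity_folds,
            seed=seeds["similarity"],
        )
        query_nm = nm_hvg.subset_cells(~holdout)
        query_groups = types_kept[~holdout]
        sim_mat = sim.predict_similarity(model, query_nm, query_groups)
        sim_mat.rename_axis("group").reset_index().to_csv(
            outdir / "similarity.tsv", sep="\t", index=False, float_format=FLOAT_FMT
        )
        manifest.record("similarity", time.perf_counter() - t0,
                        [outdir / "similarity.tsv"])

    manifest.write(outdir / "manifest.json")
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    return d


# ---------------------------------------------------------------------
# fixtures used by the test suite and the examples
# ---------------------------------------------------------------------

def make_fixtures(seed: int, outdir: str | Path) -> Path:
    """Write the miniature, hand-checkable inputs the tests exercise:
    a 5-cell QC toy, a rank-2 non-negative matrix, and a step-profile
    chromosome for smoothing."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # QC toy: detected-gene counts 100, 1000, 1000, 1000, 5000
    n_genes = 6000
    rows = []
    for detected in [100, 1000, 1000, 1000, 5000]:
        v = np.zeros(n_genes, dtype=np.int64)
        v[rng.choice(n_genes, size=detected, replace=False)] = 1
        rows.append(v)
    import scipy.sparse as sp

    cm = CountMatrix(
        values=sp.csr_matrix(np.array(rows)),
        cell_ids=[f"C{i}" for i in range(5)],
        gene_ids=[f"G{i:04d}" for i in range(n_genes)],
        cell_meta=pd.DataFrame({"sample_id": ["S1"] * 5}),
    )
    write_counts_dir(cm, outdir / "qc_toy")

    w0 = rng.random((30, 2))
    h0 = rng.random((2, 12))
    np.savetxt(outdir / "rank2.tsv", w0 @ h0, delimiter="\t", fmt="%.17g")

    step = np.concatenate([np.full(100, -1.0), np.full(100, 1.0)])
    np.savetxt(outdir / "cnv_step.tsv", step[None, :], delimiter="\t", fmt="%.3g")
    return outdir
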