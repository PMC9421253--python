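"""Ground-truthed synthetic snRNA-seq cohort generator.

The generator emulates the statistical structure the downstream analysis
assumes in a tumor cohort of two mutation groups (RET and SDHB):

* a mixture of cell compartments (neuroendocrine tumor cells, immune,
  stromal, a small "other" fraction) with canonical marker genes and
  broader per-type expression signatures;
* patient-specific tumor transcriptomes (a private baseline shift on a
  random gene subset of each sample's tumor cells);
* a set of shared transcriptional programs, each a fixed gene set that
  is multiplicatively boosted in the tumor cells where it is active,
  with per-mutation-group activation probabilities;
* chromosomal dosage segments acting multiplicatively on tumor-cell
  gene means — by default a universal loss on arm 1p plus one private
  segment per sample — over a miniature genome (4 chromosomes with p/q
  arms) large enough to exercise a 101-gene smoothing window.

Counts are overdispersed gamma-Poisson draws conditioned on a log-normal
library size: each cell's total is drawn from the configured log-normal
and allocated across genes by a gamma-tilted multinomial, which keeps
the per-cell totals exactly on the configured distribution while giving
genes negative-binomial-like noise. Every planted structure is recorded
in a :class:`GroundTruth` object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .data import CountMatrix, GeneAnnotation, NormalizedMatrix

__all__ = [
    "ProgramActivity",
    "CNVSegment",
    "CohortConfig",
    "GroundTruth",
    "default_config",
    "generate_cohort",
    "synthetic_reference",
    "synthetic_query",
]

ALL_TUMOR = "all_tumor"

DEFAULT_MARKER_PANELS = {
    "neuroendocrine": ["TH", "DBH", "CHGB"],
    "immune": ["PTPRC", "CD163", "CD247"],
    "stromal": ["COL4A1", "COL1A2"],
    "other": ["CYP11A1", "CYP11B1"],
}


class ConfigError(ValueError):
    """Raised for inconsistent cohort configurations."""


@dataclass(frozen=True)
class ProgramActivity:
    """Activation probability per mutation group and the multiplicative
    boost applied to program genes in active tumor cells."""

    p_active: dict  # mutation_group -> probability
    fold: float = 4.0

    def prob(self, group: str) -> float:
        return float(self.p_active.get(group, 0.0))


@dataclass(frozen=True)
class CNVSegment:
    """A chromosomal dosage change: ``arm`` (e.g. ``"1p"``), multiplicative
    ``dosage`` on gene means, and the affected samples (``"all_tumor"``
    or an explicit tuple of sample ids). Only tumor cells carry it."""

    arm: str
    dosage: float
    samples: object = ALL_TUMOR

    def affects(self, sample_id: str) -> bool:
        return self.samples == ALL_TUMOR or sample_id in self.samples


@dataclass
class CohortConfig:
    n_samples_ret: int = 5
    n_samples_sdhb: int = 6
    cells_per_sample: int = 1000
    n_genes: int = 2000
    celltype_fractions: dict = field(
        default_factory=lambda: {
            "neuroendocrine": 0.63, "immune": 0.16, "stromal": 0.16, "other": 0.05,
        }
    )
    n_shared_programs: int = 10
    program_size: int = 50
    program_activity: dict = field(default_factory=dict)  # name -> ProgramActivity
    cnv_segments: list = field(default_factory=list)
    marker_panels: dict = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_MARKER_PANELS.items()}
    )
    libsize_lognormal: tuple = (8.0, 0.35)  # mean ~3300 counts/cell
    nb_dispersion: float = 20.0  # gamma shape; larger = less overdispersed
    seed: int = 0
    # structure beyond the named fields
    n_chromosomes: int = 4
    p_arm_fraction: float = 0.4
    marker_fold: float = 10.0
    signature_size: int = 60  # extra per-type signature genes
    signature_fold: float = 4.0
    private_shift_genes: int = 80  # per-sample private tumor program
    private_shift_fold: float = 2.0
    excluded_samples: tuple = ()  # emulates the non-representative donor

    # -- derived -------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [f"RET_P{i + 1}" for i in range(self.n_samples_ret)] + [
            f"SDHB_P{i + 1}" for i in range(self.n_samples_sdhb)
        ]

    @property
    def analyzed_samples(self) -> list[str]:
        excl = set(self.excluded_samples)
        return [s for s in self.sample_ids if s not in excl]

    def group_of(self, sample_id: str) -> str:
        return "RET" if sample_id.startswith("RET") else "SDHB"

    def validate(self) -> None:
        tot = sum(self.celltype_fractions.values())
        if abs(tot - 1.0) > 1e-9:
            raise ConfigError(f"celltype_fractions sum to {tot}, expected 1")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        for seg in self.cnv_segments:
            if seg.dosage <= 0:
                raise ConfigError(f"dosage must be > 0 (segment {seg.arm})")
        n_special = (
            self.n_shared_programs * self.program_size
            + sum(len(v) for v in self.marker_panels.values())
            + self.signature_size * len(self.marker_panels)
        )
        if self.n_shared_programs * self.program_size > self.n_genes:
            raise ConfigError(
                f"{self.n_shared_programs} programs x {self.program_size} genes "
                f"exceed n_genes={self.n_genes}"
            )
        if n_special > self.n_genes:
            raise ConfigError(
                f"planted structure needs {n_special} genes but n_genes={self.n_genes}"
            )
        unknown = set(self.excluded_samples) - set(self.sample_ids)
        if unknown:
            raise ConfigError(f"excluded_samples not in cohort: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery checks."""

    cell_table: pd.DataFrame  # cell_id, sample_id, mutation_group, true_cell_type, true_program_ids
    program_genes: dict  # program name -> list of gene ids
    cnv_segments: list  # CNVSegment objects actually applied
    sample_segments: dict  # sample_id -> list of CNVSegment
    signature_genes: dict  # cell type -> list of gene ids
    private_genes: dict  # sample_id -> list of gene ids

    def active_programs(self, cell_index: int) -> list[str]:
        raw = self.cell_table["true_program_ids"].iloc[cell_index]
        return raw.split(",") if raw else []

    def program_membership(self) -> pd.Series:
        """gene_id -> program name for planted program genes."""
        rows = {g: p for p, genes in self.program_genes.items() for g in genes}
        return pd.Series(rows, name="program")

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cell_table.to_csv(outdir / "truth_cells.tsv", sep="\t", index=False)
        self.program_membership().rename_axis("gene_id").reset_index().to_csv(
            outdir / "truth_program_genes.tsv", sep="\t", index=False
        )
        seg_rows = [
            {"sample_id": s, "arm": seg.arm, "dosage": seg.dosage}
            for s, segs in self.sample_segments.items()
            for seg in segs
        ]
        pd.DataFrame(seg_rows).to_csv(
            outdir / "truth_cnv_segments.tsv", sep="\t", index=False
        )
        return outdir


def default_config(seed: int = 0) -> CohortConfig:
    """Cohort configuration emulating the analyzed study cohort.

    Eleven tumor samples (5 RET + 6 SDHB) are generated and one RET
    donor is flagged for exclusion, leaving 10 analyzed samples
    (4 RET + 6 SDHB). Compartment fractions are ~63% neuroendocrine,
    16% immune, 16% stromal and 5% other. Ten shared transcriptional
    programs are planted — four active in both mutation groups, three
    RET-enriched, three SDHB-enriched — and every tumor sample carries
    a universal 0.5x dosage loss on chromosome arm 1p plus one private
    dosage segment.
    """
    cfg = CohortConfig(seed=seed, excluded_samples=("RET_P5",))
    activity = {}
    for i in range(1, 5):
        activity[f"P{i}"] = ProgramActivity({"RET": 0.50, "SDHB": 0.50})
    for i in range(5, 8):
        activity[f"P{i}"] = ProgramActivity({"RET": 0.50, "SDHB": 0.05})
    for i in range(8, 11):
        activity[f"P{i}"] = ProgramActivity({"RET": 0.05, "SDHB": 0.50})
    cfg.program_activity = activity

    segments = [CNVSegment("1p", 0.5, ALL_TUMOR)]
    private_arms = ["2q", "3p", "4q", "2p", "3q", "4p"]
    for i, sample in enumerate(cfg.sample_ids):
        arm = private_arms[i % len(private_arms)]
        dosage = 0.5 if i % 2 == 0 else 1.5
        segments.append(CNVSegment(arm, dosage, (sample,)))
    cfg.cnv_segments = segments
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------

def _build_genome(cfg: CohortConfig) -> tuple[GeneAnnotation, np.ndarray]:
    """Lay out n_genes over n_chromosomes with p/q arms; returns the
    annotation (canonical order) and the gene id array in that order."""
    per_chrom = cfg.n_genes // cfg.n_chromosomes
    rows = []
    g = 0
    for c in range(1, cfg.n_chromosomes + 1):
        n_here = per_chrom + (cfg.n_genes % cfg.n_chromosomes if c == cfg.n_chromosomes else 0)
        n_p = int(round(cfg.p_arm_fraction * n_here))
        for j in range(n_here):
            arm = f"{c}p" if j < n_p else f"{c}q"
            start = j * 10_000 + 1
            rows.append(
                {"gene_id": f"G{g:04d}", "chromosome": f"chr{c}",
                 "start": start, "end": start + 999, "arm": arm}
            )
            g += 1
    ann = GeneAnnotation(pd.DataFrame(rows))
    return ann, ann.gene_ids.copy()


def _assign_special_genes(
    cfg: CohortConfig, ann: GeneAnnotation, rng: np.random.Generator
) -> tuple[GeneAnnotation, dict, dict, dict]:
    """Rename marker genes to their canonical symbols and pick disjoint
    signature / program gene sets.

    Program and private-shift genes are drawn outside arm 1p so the
    planted universal dosage loss and the planted expression programs
    stay orthogonal signals.
    """
    table = ann.table.copy()
    gene_ids = table["gene_id"].to_numpy(dtype=object)
    arms = table["arm"].to_numpy(dtype=object)
    n = len(gene_ids)

    taken = np.zeros(n, dtype=bool)
    off_1p = arms != "1p"

    def draw(k: int, mask: np.ndarray) -> np.ndarray:
        pool = np.flatnonzero(mask & ~taken)
        if len(pool) < k:
            raise ConfigError("not enough genes for planted structure")
        idx = rng.choice(pool, size=k, replace=False)
        taken[idx] = True
        return np.sort(idx)

    # markers: renamed to canonical symbols, spread anywhere off 1p
    marker_idx: dict[str, np.ndarray] = {}
    for ctype, panel in cfg.marker_panels.items():
        idx = draw(len(panel), off_1p)
        for pos, name in zip(idx, panel):
            gene_ids[pos] = name
        marker_idx[ctype] = idx
    table["gene_id"] = gene_ids

    signature_idx = {
        ctype: draw(cfg.signature_size, off_1p) for ctype in cfg.marker_panels
    }
    program_names = list(cfg.program_activity) or [
        f"P{i + 1}" for i in range(cfg.n_shared_programs)
    ]
    program_idx = {name: draw(cfg.program_size, off_1p) for name in program_names}

    # re-canonicalize (renaming never reorders: coordinates unchanged)
    ann2 = GeneAnnotation(table)
    return ann2, marker_idx, signature_idx, program_idx


# ---------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------

def generate_cohort(
    cfg: CohortConfig,
) -> tuple[CountMatrix, GeneAnnotation, GroundTruth]:
    """Draw a full cohort with planted ground truth.

    Per-gene means are ``library_share x baseline(type, gene) x program
    boost x CNV dosage``; counts come from a gamma-tilted multinomial
    conditioned on a log-normal per-cell total. Fixing ``cfg.seed``
    fixes the cohort bit-for-bit.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ann, _ = _build_genome(cfg)
    ann, marker_idx, signature_idx, program_idx = _assign_special_genes(cfg, ann, rng)
    gene_ids = ann.gene_ids
    arms = ann.table["arm"].to_numpy(dtype=object)
    n_genes = len(gene_ids)

    # baseline relative abundance, heavy-tailed; planted genes pinned to
    # a moderate level so their signal is neither drowned nor dominant
    rho = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    mid = float(np.median(rho))
    for idx in signature_idx.values():
        rho[idx] = mid
    for idx in program_idx.values():
        rho[idx] = mid
    for idx in marker_idx.values():
        rho[idx] = mid * 2.0

    types = list(cfg.celltype_fractions)
    fractions = np.array([cfg.celltype_fractions[t] for t in types])

    # per-type baseline multiplier rows
    type_mult = {}
    for t in types:
        m = np.ones(n_genes)
        for t2 in types:
            own = t2 == t
            m[marker_idx[t2]] *= cfg.marker_fold if own else 0.1
            m[signature_idx[t2]] *= cfg.signature_fold if own else 1.0
        type_mult[t] = m

    # per-sample private tumor shift (patient-specific transcriptome)
    eligible = np.ones(n_genes, dtype=bool)
    eligible[np.flatnonzero(arms == "1p")] = False
    for idx in marker_idx.values():
        eligible[idx] = False
    for idx in signature_idx.values():
        eligible[idx] = False
    for idx in program_idx.values():
        eligible[idx] = False
    private_idx = {}
    for sample in cfg.sample_ids:
        pool = np.flatnonzero(eligible)
        k = min(cfg.private_shift_genes, len(pool))
        private_idx[sample] = np.sort(rng.choice(pool, size=k, replace=False))

    # per-sample dosage vectors (tumor cells only)
    sample_segments = {s: [] for s in cfg.sample_ids}
    dosage = {}
    for sample in cfg.sample_ids:
        d = np.ones(n_genes)
        for seg in cfg.cnv_segments:
            if seg.affects(sample):
                d[arms == seg.arm] *= seg.dosage
                sample_segments[sample].append(seg)
        dosage[sample] = d

    program_names = list(program_idx)
    mu_lib, sigma_lib = cfg.libsize_lognormal

    blocks: list[sp.csr_matrix] = []
    meta_rows = []
    cell_ids = []
    for sample in cfg.sample_ids:
        group = cfg.group_of(sample)
        n_cells = cfg.cells_per_sample
        if n_cells == 0:
            continue
        cell_types = rng.choice(len(types), size=n_cells, p=fractions)
        mu = np.empty((n_cells, n_genes))
        for ti, t in enumerate(types):
            mu[cell_types == ti] = rho * type_mult[t]
        is_tumor = cell_types == types.index("neuroendocrine") if "neuroendocrine" in types else np.zeros(n_cells, bool)

        # private shift + planted programs + CNV dosage on tumor cells
        mu[np.ix_(is_tumor, private_idx[sample])] *= cfg.private_shift_fold
        active = np.zeros((n_cells, len(program_names)), dtype=bool)
        for pi, pname in enumerate(program_names):
            act = cfg.program_activity.get(
                pname, ProgramActivity({"RET": 0.0, "SDHB": 0.0})
            )
            on = is_tumor & (rng.random(n_cells) < act.prob(group))
            active[:, pi] = on
            mu[np.ix_(on, program_idx[pname])] *= act.fold
        mu[is_tumor] *= dosage[sample][None, :]

        totals = np.maximum(
            1, np.round(rng.lognormal(mu_lib, sigma_lib, size=n_cells))
        ).astype(np.int64)
        tilt = rng.gamma(cfg.nb_dispersion, 1.0 / cfg.nb_dispersion, size=mu.shape)
        rates = mu * tilt
        counts = np.empty((n_cells, n_genes), dtype=np.int32)
        for c in range(n_cells):
            p = rates[c] / rates[c].sum()
            counts[c] = rng.multinomial(totals[c], p)
        blocks.append(sp.csr_matrix(counts))

        for c in range(n_cells):
            progs = [program_names[pi] for pi in np.flatnonzero(active[c])]
            cell_ids.append(f"{sample}_C{c:04d}")
            meta_rows.append(
                {
                    "sample_id": sample,
                    "mutation_group": group,
                    "true_cell_type": types[cell_types[c]],
                    "true_program_ids": ",".join(progs),
                }
            )

    if blocks:
        values = sp.vstack(blocks).tocsr()
    else:
        values = sp.csr_matrix((0, n_genes), dtype=np.int32)
    meta = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "mutation_group", "true_cell_type", "true_program_ids"],
    )
    cm = CountMatrix(
        values=values, cell_ids=np.array(cell_ids, dtype=object),
        gene_ids=gene_ids, cell_meta=meta,
    )
    truth = GroundTruth(
        cell_table=pd.concat(
            [pd.DataFrame({"cell_id": cell_ids}), meta], axis=1
        ),
        program_genes={p: list(gene_ids[idx]) for p, idx in program_idx.items()},
        cnv_segments=list(cfg.cnv_segments),
        sample_segments=sample_segments,
        signature_genes={t: list(gene_ids[idx]) for t, idx in signature_idx.items()},
        private_genes={s: list(gene_ids[idx]) for s, idx in private_idx.items()},
    )
    return cm, ann, truth


# ---------------------------------------------------------------------
# small labeled reference / query pair for similarity mapping
# ---------------------------------------------------------------------

def _typed_expression(
    rng: np.random.Generator,
    type_of_cell: np.ndarray,
    types: list[str],
    n_genes: int,
    markers_per_type: int,
    fold: float,
    noise_sd: float = 0.3,
) -> np.ndarray:
    """Log-scale expression with a disjoint boosted marker block per type;
    a cell typed ``a+b`` expresses both blocks at half strength."""
    base = rng.normal(1.0, noise_sd, size=(len(type_of_cell), n_genes))
    for ti, t in enumerate(types):
        block = slice(ti * markers_per_type, (ti + 1) * markers_per_type)
        for ci, ct in enumerate(type_of_cell):
            parts = ct.split("+")
            if t in parts:
                base[ci, block] += np.log(fold) / len(parts)
    return np.clip(base, 0.0, None)


def synthetic_reference(
    types: tuple = ("sympathoblast", "bridge", "chromaffin"),
    cells_per_type: int = 120,
    n_genes: int = 300,
    markers_per_type: int = 25,
    fold: float = 8.0,
    seed: int = 0,
) -> tuple[NormalizedMatrix, np.ndarray]:
    """A separable labeled reference: each type over-expresses its own
    disjoint marker block. Returns (normalized matrix, labels)."""
    rng = np.random.default_rng(seed)
    labels = np.repeat(list(types), cells_per_type)
    x = _typed_expression(rng, labels, list(types), n_genes, markers_per_type, fold)
    gene_ids = np.array([f"RG{i:04d}" for i in range(n_genes)], dtype=object)
    cell_ids = np.array([f"ref_C{i:04d}" for i in range(len(labels))], dtype=object)
    nm = NormalizedMatrix(
        values=x, cell_ids=cell_ids, gene_ids=gene_ids,
        cell_meta=pd.DataFrame({"cell_type": labels}),
        provenance={"source": "synthetic_reference"},
    )
    return nm, labels


def synthetic_query(
    types: tuple = ("sympathoblast", "bridge", "chromaffin"),
    cells_per_group: int = 80,
    n_genes: int = 300,
    markers_per_type: int = 25,
    fold: float = 8.0,
    mixture_of: tuple = ("sympathoblast", "chromaffin"),
    seed: int = 1,
) -> tuple[NormalizedMatrix, np.ndarray]:
    """Query cells with one group per reference type plus a group of
    intermediate cells co-expressing two types' markers at half
    strength. Returns (normalized matrix, group labels)."""
    rng = np.random.default_rng(seed)
    groups = [f"{t}_like" for t in types] + ["mixture"]
    cell_type = list(np.repeat(list(types), cells_per_group)) + ["+".join(mixture_of)] * cells_per_group
    x = _typed_expression(
        rng, np.array(cell_type, dtype=object), list(types), n_genes,
        markers_per_type, fold,
    )
    labels = np.repeat(groups, cells_per_group)
    gene_ids = np.array([f"RG{i:04d}" for i in range(n_genes)], dtype=object)
    cell_ids = np.array([f"qry_C{i:04d}" for i in range(len(labels))], dtype=object)
    nm = NormalizedMatrix(
        values=x, cell_ids=cell_ids, gene_ids=gene_ids,
        cell_meta=pd.DataFrame({"group": labels}),
        provenance={"source": "synthetic_query"},
    )
    return nm, labels
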