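"""Per-sample NMF programs clustered into cohort metaprograms.

Each analyzed sample's tumor cells are factorized into 28 programs
(top-50 genes per factor); all tumor cells are scored for every program
with a binned-control module score; programs are clustered on the
Pearson correlation of their score profiles (Ward linkage, silhouette
auto-cut) and compared between mutation groups.
"""

import numpy as np
import pandas as pd

import pcpghet as p

cfg = p.default_config(seed=0)
cfg.cells_per_sample = 400
cm, ann, truth = p.generate_cohort(cfg)
nm = p.normalize_log(p.filter_cells(cm))

samples = nm.cell_meta["sample_id"].to_numpy(object)
types = nm.cell_meta["true_cell_type"].to_numpy(object)
keep = ~np.isin(samples, list(cfg.excluded_samples))
hvg = p.select_hvg(nm, n=1200)
nm_tumor = nm.subset_cells(keep & (types == "neuroendocrine")).subset_genes(
    list(hvg.genes)
)

programs = p.ProgramSet()
for si, sample in enumerate(sorted(nm_tumor.cell_meta["sample_id"].unique())):
    nm_s = p.metaprograms.prepare_nmf_input(
        nm_tumor.subset_cells(nm_tumor.cell_meta["sample_id"].to_numpy() == sample)
    )
    result = p.nmf_factorize(nm_s, k=28, seed=100 + si, sample_id=sample)
    programs.programs.extend(p.extract_programs(result, top_n=50).programs)
print(f"{len(programs)} programs from "
      f"{nm_tumor.cell_meta['sample_id'].nunique()} samples")

scores = p.score_all_programs(nm_tumor, programs, seed=7)
metaset = p.cluster_metaprograms(scores, programs, n_meta="auto")
print(f"auto silhouette cut: {metaset.n_meta} metaprograms")
sizes = metaset.assignment.value_counts().sort_index()
print("programs per metaprogram:", dict(sizes))

print("\ntop 5 frequency-ranked genes of M1:")
print(metaset.gene_tables[1].head(5).round(3).to_string(index=False))

meta_scores = p.score_metaprograms(nm_tumor, metaset, seed=99)
comparison = p.compare_groups(
    meta_scores, nm_tumor.cell_meta["mutation_group"].to_numpy(object)
)
print("\nRET vs SDHB per metaprogram (group-specific ones separate sharply):")
print(comparison.round(4).to_string(index=False))
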