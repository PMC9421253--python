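# Methods

`pcpghet` reimplements, as a tested pipeline, a single-nucleus RNA-seq
heterogeneity analysis of pheochromocytoma/paraganglioma (PCPG) cohorts
with RET and SDHB germline mutations: quality filtering, normalization,
clustering and cell-type annotation, expression-inferred copy number,
per-sample NMF transcriptional programs clustered into cohort
metaprograms, mutation-group comparison, and elastic-net
logistic-regression similarity to a labeled reference. Because the real
cohort is controlled-access, the package ships a synthetic cohort
generator that plants — with full ground truth — the structures the
analysis is designed to recover. This note records the models, the
defaults and why, and what the synthetic validation does and does not
demonstrate.

## QC and normalization

Cells are filtered per library: a cell is kept when its number of
detected genes lies within [10%, 250%] of the library's mean detected
genes, the mean being computed once on the unfiltered library. "Gene
count" is read as detected genes (nFeature), not total UMIs. The filter
is a deliberate single pass; re-running it recomputes the mean on the
survivors and may remove further cells (a property the tests assert
rather than hide).

Normalization is the standard library-size transform: counts are scaled
to 10 000 per cell and ln(1 + x)-transformed (natural log, pseudocount
1 — the dominant convention for "log-normalized" counts). Variable genes
are ranked by a binned dispersion statistic: per-gene variance of the
log-normalized values, z-standardized within 20 equal-frequency bins of
mean expression; exactly-constant genes are forced to the bottom. The
number of variable genes defaults to 4000 (clamped to the gene count on
small genomes). Scaling for PCA is a per-gene z-score (population sd,
constant genes map to 0) clipped at ±10 to keep outlier cells from
dominating components.

## Clustering and annotation

PCA (15 components, randomized SVD, sign fixed so each component's
largest-magnitude loading is positive) feeds a shared-nearest-neighbor
graph: 20 nearest neighbors per cell (self included in the neighbor
set), edge weight the Jaccard overlap of neighbor sets, edges below
1/15 pruned. The graph is partitioned by maximizing resolution-scaled
modularity at resolution 0.3 (Louvain-style local moving with Leiden
refinement via `leidenalg`, seeded; labels renumbered largest-first).

Markers are detected one cluster vs the rest: genes detected in ≥25% of
the cluster's cells and with |ln fold change| ≥ 0.25 (fold changes on
mean expm1-normalized expression with pseudocount 1) are tested by
Wilcoxon rank-sum — exact for tiny tie-free groups, tie-corrected
normal approximation otherwise — Bonferroni-adjusted over all genes,
and reported when adjusted p < 0.05 and |log2FC| > 1.2. The two
threshold stages are applied sequentially, as two distinct filters.

Cell types are assigned per cluster by the marker panel (e.g. TH/DBH/
CHGB for neuroendocrine, PTPRC/CD163/CD247 immune, COL4A1/COL1A2
stromal, CYP11A1/CYP11B1 adrenocortical-like "other") with the highest
mean normalized expression; exact ties break by panel order and are
flagged ambiguous.

## Inferred copy number

Log-normalized expression, with genes in genomic order (1-based GTF-
style coordinates; chromosomes in plain string order; ties broken by
gene id), is centered on the reference cells' per-gene mean — reference
cells are the non-tumor compartments, and they are centered and scored
too, so aberrations in the reference would remain visible — and clamped
to ±3. A 101-gene moving average is applied per cell within each
chromosome (the window shrinks symmetrically at chromosome ends and
never crosses a boundary), followed by per-cell median re-centering
(median, not mean, for robustness to large aberrations).

Smoothed profiles are averaged within groups — each sample's tumor
population plus each reference cell type; all groups need ≥10 cells —
and each group profile is segmented per chromosome by Viterbi decoding
of a symmetric 3-state Gaussian HMM: state means (−δ, 0, +δ) with
δ = 0.15 on the smoothed log scale, shared emission sd estimated as the
sd of the reference cells' smoothed values, uniform start, self-
transition 0.99 with symmetric switching. This reduces the published
"i3" machinery to its loss/neutral/gain semantics at desk scale; δ and
the self-transition are configurable.

Before decoding, group-mean values within 1.5 reference-sds of zero are
set to zero (`denoise_sigma`, 0 disables). This step is essential, not
cosmetic: tumor transcriptional programs leave sustained ±0.03–0.10
drifts in copy-neutral regions that smoothing cannot remove (true
dosage signal is ±0.3–0.5 at 0.5×/1.5× dosage), and without thresholding
the HMM faithfully segments that drift. Expression-CNV practice applies
the same kind of dynamic denoising for the same reason.

Arm-level calls label an arm loss (gain) when more than half of its
genes are in the loss (gain) state.

## NMF programs and metaprograms

For each analyzed tumor sample, the log-normalized tumor-cell ×
variable-gene submatrix is factorized with k = 28 non-negative factors
by multiplicative updates from a seeded uniform-random initialization
scaled by √(mean(X)/k); the Frobenius loss is recorded every iteration
(non-increasing by construction — asserted in tests), iteration stops at
relative loss change < 1e-5 or 500 iterations, and W columns are
rescaled to unit L2 with compensation in H. Each factor's program is
its top 50 genes by W loading (gene-id tie-break; factors with fewer
positive loadings yield shorter programs, with a warning).

Input transform: by default each gene's per-sample minimum is
subtracted before factorization (`baseline_shift`). All cells express a
large common baseline; without the shift a noticeable share of the 28
factors per sample reconstructs that baseline, and those factors —
loaded on the same highly expressed genes in every sample — form a
spurious cross-sample "housekeeping" metaprogram. Subtracting the
per-gene minimum removes the shared component while preserving
non-negativity; factorizing the raw log-normalized values remains
available as `baseline_shift=False`.

All tumor cells are scored for every program with a binned-control
module score: genes are placed in 25 equal-frequency bins by mean
expression, each program gene draws 100 control genes (with
replacement) from its bin, and the score is mean program-gene
expression minus mean pooled-control expression. The binning is
computed once and shared across programs, and each program's control
draw is seeded as master seed + program index, so adding programs never
changes existing columns. A single random gene set retains a small
gene-sampling offset; calibration (tested) means the offsets are
centered on zero over random sets, and planted-program genes separate
active from inactive cells with AUC ≥ 0.9.

Programs are clustered on the Pearson correlation of their score
columns (distance 1 − r, Ward linkage). Programs whose score column is
(near-)constant — sd below half the median column sd — are dropped
first: they discriminate no cell state and their correlations are
noise-driven (scale-invariant Pearson would otherwise cluster them by
shared incidental genes). The dendrogram is cut, by default, at the
K ∈ [2, 15] with the largest mean silhouette on the precomputed
distances (ties to the smallest K); a manual `n_meta` override exists.
The published analysis fixed ten metaprograms by inspection; the
silhouette cut is this package's own explicit decision rule, and on the
default synthetic cohort it recovers the planted ten. Each
metaprogram's genes are ranked by their frequency of presence among the
constituent programs (ties by mean within-program loading rank, then
gene id); cells are re-scored on each metaprogram's top 50
frequency-ranked genes, and the per-cell scores are compared RET vs
SDHB by two-sided Wilcoxon rank-sum.

## Similarity to a labeled reference

One binomial logistic regression per reference type (one-vs-rest) with
elastic-net penalty λ[α‖β‖₁ + (1−α)/2 ‖β‖₂²], α = 0.6. Features are
standardized with the reference's means and sds; query cells are
standardized with those same reference statistics (similarity is
measured in reference space), with model genes missing from the query
imputed at the reference mean. λ defaults to "auto": per type, a small
λ grid is scored by 5-fold cross-validated deviance on a seeded
stratified split (coarse fits), and the final model is refitted on all
reference cells by saga descent to 1e-6. Per-cell logits (intercept +
β·x) are averaged within each query group; probability averaging is
available as an option. One-vs-rest rather than multinomial keeps each
type's similarity independent, matching the per-type semantics of the
approach.

The pipeline stage demonstrates the mapping with a label-stratified
holdout of the cohort itself (annotated types as reference labels, at
most 100 reference cells per type, top 600 variable genes as features);
the `synthetic_reference`/`synthetic_query` pair (sympathoblast /
bridge / chromaffin-like types with disjoint marker blocks, plus a
mixed query group co-expressing two types at half strength) exercises
the intermediate-similarity pattern.

## The synthetic cohort generator

The generator emulates the analyzed study design: 11 tumor samples
(5 RET + 6 SDHB), one RET donor flagged non-representative and excluded,
leaving 10 analyzed samples; compartment fractions 0.63 neuroendocrine,
0.16 immune, 0.16 stromal, 0.05 other; 1000 cells per sample at desk
scale; a miniature genome of 2000 genes on 4 chromosomes with p/q arms
(large enough to exercise the 101-gene window); ten shared planted
programs of 50 genes each; a universal 0.5× dosage loss on arm 1p in
every tumor sample plus one private dosage segment (0.5× or 1.5×) per
sample.

Counts are gamma-Poisson draws conditioned on a log-normal library
size: each cell's total is drawn from LogNormal(8.0, 0.35) (~3300
counts) and allocated across genes by a multinomial whose probabilities
are the cell's mean vector tilted by per-gene Gamma(θ, 1/θ) noise with
θ = 20. Conditioning makes the per-cell total distribution exactly the
configured log-normal (a tested invariant) while keeping gene-level
negative-binomial-like overdispersion; it is the conditional form of an
unconditional gamma-Poisson model. Mean structure is multiplicative:
baseline gene abundance (heavy-tailed log-normal, with planted genes
pinned to moderate levels) × cell-type effects (marker genes ×10 in
their own type, ×0.1 elsewhere; 60 broader signature genes ×4 per
type) × a per-sample private shift (×2 on 80 genes of each sample's
tumor cells — the patient-specific transcriptome) × program boosts
(×4 on a program's genes in tumor cells where it is active) × CNV
dosage on segment genes of tumor cells.

Program activation is Bernoulli per tumor cell: four programs are
active at p = 0.5 in both mutation groups, three at 0.5/0.05
(RET-enriched) and three at 0.05/0.5 (SDHB-enriched). These
probabilities and the ×4 boost are chosen for reliable recovery of the
planted structure by the k = 28 factorization — dense activation means
the factor budget is consumed by program combinations rather than
noise — and are freely tunable. Program, signature and private-shift
genes are drawn outside arm 1p so the universal dosage loss and the
expression programs remain orthogonal planted signals; private CNV
segments on other arms may overlap program genes, which the truth
tables record.

What the generator does not emulate: ambient RNA, doublets, batch or
chemistry effects, realistic gene-length or GC structure, subclonal CNV
heterogeneity, or the real cohort's per-nucleus gene counts. Passing
the recovery tests therefore shows the implementation recovers the
structures the methods assume, under the stated noise model — not that
the methods are robust to every artifact of real droplet data.

## Pipeline, seeds, determinism

One master seed derives, via `numpy.random.SeedSequence` spawning, the
seeds of every stochastic stage (cohort generation, PCA, graph
clustering, control-gene sampling, CV folds, holdout). Stage order:
input/simulate → QC → normalize/HVG/scale → PCA → clustering → markers
→ annotation → composition → tumor selection (annotated neuroendocrine
cells; excluded samples dropped entirely from downstream analysis) →
inferred CNV (groups: per-sample tumor populations + reference types)
→ per-sample NMF → cohort scoring → metaprograms → group comparison →
similarity. Every stage writes TSV artifacts whose SHA-256 hashes are
recorded in a run manifest; identical config and seed reproduce
identical hashes (tested).

Problem sizes in the shipped configuration — 2000 genes, 1000 cells per
sample, 1200 variable genes, 600 similarity features, at most 100
reference cells per type — are the package's desk-scale choices for the
miniature genome; the full-scale study parameters (4000 HVGs etc.)
remain the defaults wherever they are not size-bound.

## Known limitations

* The 3-state HMM is a deliberate reduction of the published tool's
  Bayesian machinery; it calls arm-scale dosage on group-averaged
  profiles and is not a subclone caller.
* The silhouette auto-cut is a decision rule this package defines; on
  real data, where program structure is not planted, the chosen K
  should be reviewed against the dendrogram.
* Wilcoxon p-values at cohort scale use the tie-corrected normal
  approximation; exact p-values are used only for tiny tie-free groups.
* The near-constant score-column threshold (half the median column sd)
  is a heuristic; pathological score distributions could require
  adjusting it.
* The saga solver may hit its iteration cap on perfectly separable
  reference data at tight tolerance; coefficients are then still
  well-regularized but formally unconverged (a warning is emitted).
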