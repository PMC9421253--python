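"""Expression-inferred copy number: reference centering, genomic
moving-average smoothing, and 3-state (loss/neutral/gain) HMM calls.

The procedure mirrors expression-based CNV inference practice: per-gene
expression is centered on a reference cell population (the tumor
microenvironment), clamped, smoothed along genomic gene order with a
101-gene moving average that never crosses a chromosome boundary,
re-centered per cell at its median, averaged within groups (each
sample's tumor population plus each reference type), and segmented per
chromosome by Viterbi decoding of a symmetric 3-state Gaussian HMM with
state means (-delta, 0, +delta) and a shared emission sd estimated from
the reference cells' smoothed values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GeneAnnotation, NormalizedMatrix

__all__ = ["CNVParams", "CNVProfile", "center_on_reference", "smooth_genomic",
           "viterbi_3state", "call_states", "arm_summary", "infer_cnv"]

LOSS, NEUTRAL, GAIN = -1, 0, 1
STATE_NAMES = {LOSS: "loss", NEUTRAL: "neutral", GAIN: "gain"}


@dataclass(frozen=True)
class CNVParams:
    """window: odd moving-average width in genes; clamp: bound on centered
    expression; hmm_delta: |state mean| of loss/gain on the smoothed log
    scale; p_stay: HMM self-transition probability; denoise_sigma:
    group-mean values within this many reference sds of zero are zeroed
    before decoding (suppresses residual expression drift — e.g. tumor
    programs — that smoothing cannot remove; 0 disables)."""

    window: int = 101
    clamp: float = 3.0
    hmm_delta: float = 0.15
    p_stay: float = 0.99
    denoise_sigma: float = 1.5

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 1, got {self.window}")
        if not (0 < self.p_stay < 1):
            raise ValueError(f"p_stay must be in (0,1), got {self.p_stay}")
        if self.hmm_delta <= 0:
            raise ValueError(f"hmm_delta must be > 0, got {self.hmm_delta}")
        if self.denoise_sigma < 0:
            raise ValueError(f"denoise_sigma must be >= 0, got {self.denoise_sigma}")


@dataclass
class CNVProfile:
    """Group-averaged smoothed profiles and per-gene state calls, aligned
    to the canonical gene order."""

    groups: list
    gene_ids: np.ndarray
    chromosomes: np.ndarray
    arms: np.ndarray
    smoothed: np.ndarray  # groups x genes
    states: np.ndarray  # groups x genes in {-1, 0, 1}

    def states_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, index=self.groups, columns=self.gene_ids)
        return df.replace(STATE_NAMES)


def center_on_reference(
    values: np.ndarray, reference_mask: np.ndarray, clamp: float = 3.0
) -> np.ndarray:
    """Subtract the per-gene mean over reference cells from every cell
    (reference cells included, so aberrations in the reference remain
    visible) and clamp to ``[-clamp, clamp]``."""
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if not reference_mask.any():
        raise ValueError("reference cell set is empty")
    ref_mean = values[reference_mask].mean(axis=0)
    return np.clip(values - ref_mean[None, :], -clamp, clamp)


def _smooth_block(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 1; near block edges the window
    shrinks symmetrically (position i averages i-m..i+m with
    m = min(half, i, L-1-i))."""
    n = x.shape[1]
    half = window // 2
    pos = np.arange(n)
    m = np.minimum(half, np.minimum(pos, n - 1 - pos))
    cs = np.concatenate(
        [np.zeros((x.shape[0], 1)), np.cumsum(x, axis=1)], axis=1
    )
    lo, hi = pos - m, pos + m + 1
    return (cs[:, hi] - cs[:, lo]) / (hi - lo)[None, :]


def smooth_genomic(
    centered: np.ndarray,
    chromosomes: np.ndarray,
    window: int = 101,
) -> np.ndarray:
    """Moving average along genomic order within each chromosome, then
    per-cell median re-centering across all genes.

    ``chromosomes`` gives the chromosome of each column; columns must
    already be in canonical genomic order. Smoothing is linear and, up
    to the re-centering, translation-equivariant.
    """
    chromosomes = np.asarray(chromosomes, dtype=object)
    out = np.empty_like(centered, dtype=float)
    for chrom in dict.fromkeys(chromosomes):
        cols = np.flatnonzero(chromosomes == chrom)
        if cols.size == 0:
            continue
        out[:, cols] = _smooth_block(centered[:, cols], window)
    med = np.median(out, axis=1, keepdims=True)
    return out - med


def viterbi_3state(
    profile: np.ndarray, delta: float, sd: float, p_stay: float
) -> np.ndarray:
    """Most probable loss/neutral/gain path for one group on one
    chromosome: Gaussian emissions with means (-delta, 0, +delta) and
    shared sd, uniform start, self-transition p_stay with symmetric
    switching. Returns values in {-1, 0, 1}."""
    means = np.array([-delta, 0.0, delta])
    log_emit = -0.5 * ((profile[:, None] - means[None, :]) / sd) ** 2
    log_trans = np.full((3, 3), np.log((1 - p_stay) / 2))
    np.fill_diagonal(log_trans, np.log(p_stay))
    n = len(profile)
    back = np.zeros((n, 3), dtype=np.int8)
    score = log_emit[0].copy()
    for t in range(1, n):
        cand = score[:, None] + log_trans
        back[t] = cand.argmax(axis=0)
        score = cand.max(axis=0) + log_emit[t]
    path = np.empty(n, dtype=np.int8)
    path[-1] = score.argmax()
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path - 1


def call_states(
    smoothed: np.ndarray,
    group_labels: np.ndarray,
    reference_groups: set,
    gene_ids: np.ndarray,
    chromosomes: np.ndarray,
    arms: np.ndarray,
    params: CNVParams = CNVParams(),
) -> CNVProfile:
    """Average smoothed profiles within groups and Viterbi-decode each
    group's profile chromosome by chromosome.

    The emission sd is the sd of the reference cells' smoothed values
    (cell level, pooled over genes); a degenerate sd is an error.
    Before decoding, group-mean values within ``denoise_sigma`` reference
    sds of zero are set to zero, so sustained expression drift below the
    noise floor is not segmented as dosage change. Groups with fewer
    than 10 cells are rejected.
    """
    group_labels = np.asarray(group_labels, dtype=object)
    groups = list(dict.fromkeys(group_labels))
    sizes = {g: int((group_labels == g).sum()) for g in groups}
    small = [g for g, n in sizes.items() if n < 10]
    if small:
        raise ValueError(f"groups with < 10 cells: {small}")
    missing_ref = [g for g in reference_groups if g not in groups]
    if missing_ref:
        raise ValueError(f"reference groups absent: {missing_ref}")

    ref_mask = np.isin(group_labels, list(reference_groups))
    sd = float(smoothed[ref_mask].std())
    if sd == 0:
        raise ValueError(
            "degenerate (zero) reference sd; use a larger or more diverse reference"
        )

    mean_profiles = np.vstack(
        [smoothed[group_labels == g].mean(axis=0) for g in groups]
    )
    denoised = np.where(
        np.abs(mean_profiles) < params.denoise_sigma * sd, 0.0, mean_profiles
    )
    chromosomes = np.asarray(chromosomes, dtype=object)
    states = np.zeros_like(mean_profiles, dtype=np.int8)
    for gi in range(len(groups)):
        for chrom in dict.fromkeys(chromosomes):
            cols = np.flatnonzero(chromosomes == chrom)
            states[gi, cols] = viterbi_3state(
                denoised[gi, cols], params.hmm_delta, sd, params.p_stay
            )
    return CNVProfile(
        groups=groups,
        gene_ids=np.asarray(gene_ids, dtype=object),
        chromosomes=chromosomes,
        arms=np.asarray(arms, dtype=object),
        smoothed=mean_profiles,
        states=states,
    )


def arm_summary(profile: CNVProfile) -> pd.DataFrame:
    """Arm-level calls: loss/gain where the respective gene fraction
    exceeds 0.5, else neutral. Genes without an arm label are skipped."""
    rows = []
    has_arm = ~pd.isna(profile.arms)
    arms_seen = list(dict.fromkeys(profile.arms[has_arm]))
    for gi, group in enumerate(profile.groups):
        for arm in arms_seen:
            cols = np.flatnonzero(has_arm & (profile.arms == arm))
            frac_loss = float((profile.states[gi, cols] == LOSS).mean())
            frac_gain = float((profile.states[gi, cols] == GAIN).mean())
            if frac_loss > 0.5:
                call = "loss"
            elif frac_gain > 0.5:
                call = "gain"
            else:
                call = "neutral"
            rows.append(
                {"group": group, "arm": arm, "fraction_loss": frac_loss,
                 "fraction_gain": frac_gain, "call": call}
            )
    return pd.DataFrame(rows)


def infer_cnv(
    nm: NormalizedMatrix,
    annotation: GeneAnnotation,
    group_labels: np.ndarray,
    reference_groups: set,
    params: CNVParams = CNVParams(),
) -> CNVProfile:
    """End-to-end inference on a normalized matrix: order genes
    canonically, center on the pooled reference groups' cells, smooth,
    and call states per group."""
    ordered = annotation.ordered_genes(available=nm.gene_ids)
    if ordered.size == 0:
        raise ValueError("no annotated genes present in the matrix")
    sub = nm.subset_genes(ordered)
    ann = annotation.table.set_index("gene_id").loc[list(ordered)]
    ref_mask = np.isin(np.asarray(group_labels, dtype=object), list(reference_groups))
    centered = center_on_reference(sub.values, ref_mask, clamp=params.clamp)
    smoothed = smooth_genomic(
        centered, ann["chromosome"].to_numpy(object), window=params.window
    )
    return call_states(
        smoothed, group_labels, reference_groups,
        gene_ids=ordered,
        chromosomes=ann["chromosome"].to_numpy(object),
        arms=ann["arm"].to_numpy(object),
        params=params,
    )
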