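"""Ground-truth recovery metrics for synthetic cohorts.

These utilities compare pipeline outputs against what the generator
planted: which planted program each NMF program corresponds to, how well
the metaprogram clustering groups programs by planted identity, and how
accurate the gene-wise copy-number state calls are.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

__all__ = ["program_identities", "metaprogram_recovery_ari",
           "cnv_truth_states", "cnv_state_accuracy"]


def program_identities(
    program_genes: dict, planted_genes: dict, min_overlap: int = 10
) -> pd.Series:
    """Label each extracted program with the planted program whose gene
    set overlaps its top genes the most; ``"none"`` below
    ``min_overlap`` shared genes (baseline/noise factors carry no
    planted identity)."""
    planted_sets = {k: set(v) for k, v in planted_genes.items()}
    out = {}
    for label, genes in program_genes.items():
        gs = set(genes)
        best, best_ov = "none", 0
        for name, ps in planted_sets.items():
            ov = len(gs & ps)
            if ov > best_ov:
                best, best_ov = name, ov
        out[label] = best if best_ov >= min_overlap else "none"
    return pd.Series(out, name="identity")


def metaprogram_recovery_ari(
    assignment: pd.Series, identities: pd.Series
) -> float:
    """Adjusted Rand index between the metaprogram assignment and planted
    identities, over programs with a confident identity."""
    common = assignment.index.intersection(identities.index)
    ids = identities.loc[common]
    conf = ids != "none"
    if conf.sum() < 2:
        raise ValueError("not enough confidently identified programs")
    return float(adjusted_rand_score(ids[conf], assignment.loc[common][conf]))


def cnv_truth_states(
    groups: list, gene_arms: np.ndarray, sample_segments: dict
) -> np.ndarray:
    """Expected loss/neutral/gain states per (group, gene).

    Groups named ``tumor:<sample>`` carry that sample's planted segments
    (loss where dosage < 1, gain where > 1); reference groups are
    neutral everywhere.
    """
    states = np.zeros((len(groups), len(gene_arms)), dtype=np.int8)
    for gi, group in enumerate(groups):
        if not str(group).startswith("tumor:"):
            continue
        sample = str(group).split(":", 1)[1]
        for seg in sample_segments.get(sample, []):
            mask = gene_arms == seg.arm
            states[gi, mask] = -1 if seg.dosage < 1 else (1 if seg.dosage > 1 else 0)
    return states


def cnv_state_accuracy(profile, sample_segments: dict) -> float:
    """Gene-wise fraction of correct state calls over all groups."""
    truth = cnv_truth_states(profile.groups, profile.arms, sample_segments)
    return float((profile.states == truth).mean())
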