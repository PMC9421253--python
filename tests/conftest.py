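"""Shared fixtures: a miniature cohort for structural tests and one
full default-scale pipeline run shared by the acceptance tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import pcpghet as p
from pcpghet.data import CountMatrix, NormalizedMatrix


@pytest.fixture(scope="session")
def mini_cohort():
    """Small default-structure cohort (150 cells/sample) with truth."""
    cfg = p.default_config(seed=3)
    cfg.cells_per_sample = 150
    cm, ann, truth = p.generate_cohort(cfg)
    return cfg, cm, ann, truth


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """One default-scale synthetic pipeline run (the study-conditions
    cohort: 11 samples x 1000 cells, 10 analyzed), shared by the
    acceptance tests."""
    outdir = tmp_path_factory.mktemp("full_run")
    cfg = p.pipeline.synthetic_pipeline_config(seed=11, outdir=outdir)
    manifest = p.run_pipeline(cfg)
    return cfg, manifest


def make_counts(matrix, sample_ids=None, **meta_cols) -> CountMatrix:
    """CountMatrix from a dense array with auto ids."""
    matrix = np.asarray(matrix)
    n_cells, n_genes = matrix.shape
    meta = {"sample_id": sample_ids if sample_ids is not None else ["S1"] * n_cells}
    meta.update(meta_cols)
    return CountMatrix(
        values=sp.csr_matrix(matrix),
        cell_ids=[f"C{i}" for i in range(n_cells)],
        gene_ids=[f"G{j}" for j in range(n_genes)],
        cell_meta=pd.DataFrame(meta),
    )


def make_normalized(matrix, gene_ids=None, **meta_cols) -> NormalizedMatrix:
    matrix = np.asarray(matrix, dtype=float)
    n_cells, n_genes = matrix.shape
    meta = dict(meta_cols) if meta_cols else {"sample_id": ["S1"] * n_cells}
    return NormalizedMatrix(
        values=matrix,
        cell_ids=[f"C{i}" for i in range(n_cells)],
        gene_ids=gene_ids if gene_ids is not None else [f"G{j}" for j in range(n_genes)],
        cell_meta=pd.DataFrame(meta),
        provenance={"scale_total": 10_000},
    )
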