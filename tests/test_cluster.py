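"""PCA, SNN graph clustering, marker detection, annotation, composition."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import pcpghet as p
from pcpghet.cluster import Clustering, modularity, snn_graph

from conftest import make_normalized


class TestPCA:
    def test_rank_one_structure_dominates(self):
        rng = np.random.default_rng(0)
        u, v = rng.random(200), rng.random(50)
        x = np.outer(u, v) + rng.normal(0, 1e-4, size=(200, 50))
        x = x - x.mean(axis=0)
        emb = p.pca(x, n_components=5, seed=0)
        ratio = emb.explained_variance[0] / emb.explained_variance.sum()
        assert ratio >= 0.99
        assert np.all(np.diff(emb.explained_variance) <= 1e-12)

    def test_truncation_error_bounded_by_svd(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(60, 30))
        xc = x - x.mean(axis=0)
        k = 10
        emb = p.pca(xc, n_components=k, seed=0)
        recon = emb.coords @ emb.components
        # Eckart-Young: truncation residual equals the discarded spectrum
        s = np.linalg.svd(xc, compute_uv=False)
        expected = np.sqrt((s[k:] ** 2).sum())
        got = np.linalg.norm(xc - recon)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_permuting_cells_permutes_embedding(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(40, 12))
        perm = rng.permutation(40)
        emb1 = p.pca(x, n_components=4, seed=0)
        emb2 = p.pca(x[perm], n_components=4, seed=0)
        np.testing.assert_allclose(emb2.coords, emb1.coords[perm], atol=1e-8)

    def test_invalid_components(self):
        with pytest.raises(ValueError):
            p.pca(np.ones((5, 5)), n_components=0)
        with pytest.raises(ValueError):
            p.pca(np.ones((5, 3)), n_components=4)


def _blobs(seed=0, n=120, sep=30.0):
    rng = np.random.default_rng(seed)
    centers = np.array([[0, 0], [sep, 0], [0, sep]])
    labels = np.repeat([0, 1, 2], n // 3)
    pts = centers[labels] + rng.normal(0, 1.0, size=(n, 2))
    return pts.astype(float), labels


class TestClusterGraph:
    def test_separated_blobs_recovered_exactly(self):
        pts, labels = _blobs()
        emb = p.Embedding(coords=pts, explained_variance=np.ones(2),
                          components=np.eye(2))
        clu = p.cluster_graph(emb, k_neighbors=15, resolution=0.3, seed=0)
        assert clu.n_clusters == 3
        assert adjusted_rand_score(labels, clu.labels) == 1.0

    def test_vanishing_resolution_gives_single_cluster(self):
        # limit behavior on a connected graph (a single diffuse cloud)
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 1.0, size=(120, 2))
        emb = p.Embedding(coords=pts, explained_variance=np.ones(2),
                          components=np.eye(2))
        clu = p.cluster_graph(emb, k_neighbors=15, resolution=1e-5, seed=0)
        assert clu.n_clusters == 1

    def test_partition_beats_trivial_partition(self):
        # the optimizer's objective should exceed the all-in-one and
        # singleton baselines on structured data
        pts, _ = _blobs(seed=2)
        emb = p.Embedding(coords=pts, explained_variance=np.ones(2),
                          components=np.eye(2))
        clu = p.cluster_graph(emb, k_neighbors=15, resolution=0.3, seed=0)
        adj = snn_graph(pts, k_neighbors=15)
        q_found = modularity(adj, clu.labels, resolution=0.3)
        q_one = modularity(adj, np.zeros(len(pts), dtype=int), resolution=0.3)
        q_singletons = modularity(adj, np.arange(len(pts)), resolution=0.3)
        assert q_found >= q_one and q_found >= q_singletons

    def test_too_few_cells(self):
        emb = p.Embedding(coords=np.ones((2, 2)), explained_variance=np.ones(2),
                          components=np.eye(2))
        with pytest.raises(ValueError, match="at least 3"):
            p.cluster_graph(emb)


class TestFindMarkers:
    def _two_cluster_nm(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        x = rng.random((n, 6)) * 0.5
        x[: n // 2, 0] = 3.0 + rng.random(n // 2)  # exclusive marker of cluster 0
        return make_normalized(x), Clustering(
            labels=np.repeat([0, 1], n // 2), resolution=0.3, modularity=0.0
        )

    def test_exclusive_gene_reported(self):
        nm, clu = self._two_cluster_nm()
        table = p.find_markers(nm, clu)
        row = table[(table.cluster == 0) & (table.gene == "G0")]
        assert len(row) == 1
        assert row.pct_in.iloc[0] == 1.0
        assert row.adjusted_p.iloc[0] < 0.05
        assert row.log2_fold_change.iloc[0] > 1.2

    def test_identical_distributions_not_reported(self):
        rng = np.random.default_rng(1)
        nm = make_normalized(rng.random((40, 5)))
        clu = Clustering(labels=np.repeat([0, 1], 20), resolution=0.3,
                         modularity=0.0)
        assert len(p.find_markers(nm, clu)) == 0

    def test_small_cluster_skipped_with_warning(self):
        nm, _ = self._two_cluster_nm()
        labels = np.zeros(40, dtype=int)
        labels[:2] = 1
        clu = Clustering(labels=labels, resolution=0.3, modularity=0.0)
        with pytest.warns(UserWarning, match="skipped"):
            p.find_markers(nm, clu)

    def test_needs_two_clusters(self):
        nm, _ = self._two_cluster_nm()
        clu = Clustering(labels=np.zeros(40, dtype=int), resolution=0.3,
                         modularity=0.0)
        with pytest.raises(ValueError):
            p.find_markers(nm, clu)


class TestAnnotate:
    def test_exclusive_panel_wins(self):
        x = np.zeros((20, 4))
        x[:10, 0] = 2.0  # TH-like, cluster 0
        x[10:, 2] = 2.0  # PTPRC-like, cluster 1
        nm = make_normalized(x, gene_ids=["TH", "DBH", "PTPRC", "CD163"])
        clu = Clustering(labels=np.repeat([0, 1], 10), resolution=0.3,
                         modularity=0.0)
        ann = p.annotate_celltypes(
            nm, clu, {"neuroendocrine": ["TH", "DBH"], "immune": ["PTPRC", "CD163"]}
        )
        assert list(ann.cell_type) == ["neuroendocrine", "immune"]
        assert not ann.ambiguous.any()

    def test_tie_breaks_by_panel_order_and_flags(self):
        nm = make_normalized(np.ones((6, 2)), gene_ids=["A", "B"])
        clu = Clustering(labels=np.zeros(6, dtype=int), resolution=0.3,
                         modularity=0.0)
        ann = p.annotate_celltypes(nm, clu, {"t1": ["A"], "t2": ["B"]})
        assert ann.cell_type.iloc[0] == "t1"
        assert bool(ann.ambiguous.iloc[0])

    def test_missing_genes_warned_all_missing_error(self):
        nm = make_normalized(np.ones((6, 2)), gene_ids=["A", "B"])
        clu = Clustering(labels=np.zeros(6, dtype=int), resolution=0.3,
                         modularity=0.0)
        with pytest.warns(UserWarning, match="dropping"):
            p.annotate_celltypes(nm, clu, {"t1": ["A", "ZZ"], "t2": ["B"]})
        with pytest.raises(ValueError, match="no panel gene"):
            p.annotate_celltypes(nm, clu, {"t1": ["ZZ"], "t2": ["B"]})


class TestComposition:
    def test_single_type(self):
        meta = pd.DataFrame({"sample_id": ["S1", "S1", "S2"]})
        tab = p.composition_summary(np.array(["ne"] * 3, dtype=object), meta)
        assert (tab.fraction == 1.0).all()

    def test_per_sample_fractions_average_to_overall(self):
        rng = np.random.default_rng(0)
        types = rng.choice(["a", "b", "c"], size=300)
        meta = pd.DataFrame({"sample_id": rng.choice(["S1", "S2"], size=300)})
        tab = p.composition_summary(types, meta)
        overall = tab[tab.scope == "overall"].set_index("cell_type")
        per = tab[tab.scope != "overall"]
        for ctype in overall.index:
            n = per[per.cell_type == ctype].n_cells.sum()
            assert n == overall.loc[ctype, "n_cells"]
        for scope, grp in tab.groupby("scope"):
            assert grp.fraction.sum() == pytest.approx(1.0, abs=1e-9)
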