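"""PCA, kNN/SNN graph, Louvain, and the diffusion-potential embedding."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

import ewstraj as e
from ewstraj.containers import NormalizedMatrix
from ewstraj.manifold import ManifoldError, _knn_lists


def _norm_from(values):
    g, s = values.shape
    return NormalizedMatrix(
        [f"g{i}" for i in range(g)], [f"s{i}" for i in range(s)], values, "vst"
    )


class TestPCA:
    def test_line_data_one_component(self):
        t = np.linspace(0, 1, 10)
        values = np.outer(np.array([1.0, 2.0, -1.0]), t)  # genes x samples on a line
        scores, evr = e.pca(_norm_from(values), 2)
        assert evr[0] == pytest.approx(1.0, abs=1e-10)

    def test_explained_variance_nonincreasing(self, bulk_products):
        _, evr = e.pca(bulk_products["vst"].subset_samples(bulk_products["vst"].sample_ids[:60]), 10)
        assert np.all(np.diff(evr) <= 1e-12)

    def test_scores_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(10, 8))
        scores, evr = e.pca(_norm_from(values), 3)
        X = values.T - values.T.mean(axis=0)
        vals, vecs = np.linalg.eigh(X.T @ X)
        order = np.argsort(vals)[::-1][:3]
        oracle = X @ vecs[:, order]
        for j in range(3):
            assert np.allclose(np.abs(scores.to_numpy()[:, j]), np.abs(oracle[:, j]), atol=1e-8)

    def test_overlong_request_truncates_with_warning(self):
        values = np.random.default_rng(1).normal(size=(5, 4))
        with pytest.warns(UserWarning, match="truncating"):
            scores, _ = e.pca(_norm_from(values), 10)
        assert scores.shape[1] <= 3


class TestKnnGraph:
    def test_two_blobs_disconnect(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.1, (8, 2)), rng.normal(100, 0.1, (8, 2))])
        g = e.knn_graph(X, 3)
        assert len(g.connected_components()) >= 2

    def test_jaccard_weights_bounded(self, bulk_products):
        g = e.knn_graph(bulk_products["pca"].iloc[:80], 10)
        w = np.array(g.es["weight"])
        assert np.all((w >= 0) & (w <= 1))

    def test_neighbor_lists_match_brute_force(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 3))
        ours = _knn_lists(X, 4)
        nn = NearestNeighbors(n_neighbors=5).fit(X)
        _, idx = nn.kneighbors(X)
        for i in range(12):
            assert set(ours[i]) == set(idx[i][idx[i] != i][:4])


class TestLouvain:
    def _clique_graph(self):
        import igraph as ig

        g1 = ig.Graph.Full(5)
        g2 = ig.Graph.Full(5)
        g = g1.disjoint_union(g2)
        g.vs["name"] = [str(i) for i in range(10)]
        g.es["weight"] = 1.0
        return g

    def test_two_cliques_two_clusters(self):
        cl = e.louvain(self._clique_graph(), 1.0, seed=0)
        assert cl.nunique() == 2
        assert cl[[str(i) for i in range(5)]].nunique() == 1

    def test_modularity_nonnegative_on_cliques(self):
        g = self._clique_graph()
        cl = e.louvain(g, 1.0, seed=0)
        assert g.modularity(cl[g.vs["name"]].to_list(), weights="weight") >= 0

    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(c, 0.05, (10, 2)) for c in (0, 10, 20, 30)])
        truth = np.repeat(np.arange(4), 10)
        cl = e.louvain(e.knn_graph(X, 5), 1.0, seed=0)
        assert adjusted_rand_score(truth, cl.to_numpy()) == 1.0


class TestEmbedTrajectory:
    def test_duplicate_points_identical_rows(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 4))
        X[7] = X[3]
        emb = e.embed_trajectory(pd.DataFrame(X), k=5, decay=10, t=10, n_dims=2)
        assert np.allclose(emb.coords[3], emb.coords[7], atol=1e-8)

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(40, 5)))
        a = e.embed_trajectory(X, k=8, decay=10, t=20, n_dims=3)
        b = e.embed_trajectory(X, k=8, decay=10, t=20, n_dims=3)
        assert np.array_equal(a.coords, b.coords)

    def test_one_dimensional_latent_recovered(self):
        """Samples along a latent line embed with axis 1 tracking the line."""
        cfg = e.SimConfig(
            seed=9, n_genes=600, n_pluripotent=40, n_neuroectoderm=40, n_mesoderm=40,
            n_tumor=20, n_unrelated_groups=0,
        )
        counts, meta, truth = e.simulate_bulk_compendium(cfg)
        f = e.filter_genes(counts, 0.10)
        v = e.vst(f, e.size_factors_median_ratio(f))
        scores, _ = e.pca(v, 50)
        emb = e.embed_trajectory(scores, k=15, decay=10, t=40, n_dims=2)
        rho = spearmanr(emb.coords[:, 0], truth.samples["z"])[0]
        assert abs(rho) >= 0.9

    def test_disconnected_kernel_is_error(self):
        X = np.vstack([np.zeros((5, 2)), np.full((5, 2), 1e9)])
        X += np.random.default_rng(7).normal(0, 1e-3, X.shape)
        with pytest.raises(ManifoldError, match="k"):
            e.embed_trajectory(pd.DataFrame(X), k=2, decay=40, t=5, n_dims=2)


class TestOrientAxis:
    def _emb(self):
        rng = np.random.default_rng(8)
        coords = rng.normal(size=(10, 2))
        names = [f"s{i}" for i in range(10)]
        labels = pd.Series(["meso"] * 5 + ["pluri"] * 5, index=names)
        return e.Embedding(names, coords), labels

    def test_idempotent(self):
        emb, labels = self._emb()
        once = e.orient_axis(emb, labels, "meso")
        twice = e.orient_axis(once, labels, "meso")
        assert np.array_equal(once.coords, twice.coords)

    def test_sign_invariance(self):
        emb, labels = self._emb()
        flipped = e.Embedding(list(emb.sample_ids), emb.coords * np.array([-1, 1]))
        a = e.orient_axis(emb, labels, "meso")
        b = e.orient_axis(flipped, labels, "meso")
        assert np.allclose(a.coords[:, 0], b.coords[:, 0])

    def test_anchor_group_positive_mean(self, embedding_products):
        emb = embedding_products["embedding"]
        tissue = embedding_products["meta"]["tissue"]
        meso = [s for s in emb.sample_ids if tissue[s] == "mesoderm"]
        pluri = [s for s in emb.sample_ids if tissue[s] == "pluripotent"]
        assert emb.axis1.loc[meso].mean() > emb.axis1.loc[pluri].mean()

    def test_empty_anchor_is_error(self):
        emb, labels = self._emb()
        with pytest.raises(ManifoldError):
            e.orient_axis(emb, labels, "absent")


class TestPrune:
    def test_no_unrelated_all_retained(self):
        rng = np.random.default_rng(10)
        coords = rng.normal(size=(30, 3))
        names = [f"s{i}" for i in range(30)]
        emb = e.Embedding(names, coords)
        is_tumor = pd.Series([True] * 5 + [False] * 25, index=names)
        retained = e.prune_non_trajectory(emb, is_tumor, k=10, radius=5, seed=0)
        assert set(retained) == set(names)

    def test_idempotent(self, embedding_products):
        emb3 = embedding_products["emb3"]
        is_tumor = embedding_products["meta"]["is_tumor"]
        once = e.prune_non_trajectory(emb3, is_tumor, k=15, radius=3, seed=0)
        emb_sub = e.Embedding(
            once, emb3.coords[[emb3.sample_ids.index(s) for s in once]]
        )
        twice = e.prune_non_trajectory(emb_sub, is_tumor, k=15, radius=3, seed=0)
        assert len(set(once) - set(twice)) / len(once) < 0.05

    def test_unrelated_groups_pruned(self, bulk_products):
        """Embedding all samples, off-trajectory tissue groups are removed."""
        emb = e.embed_trajectory(bulk_products["pca"], k=15, decay=10, t=40, n_dims=3)
        retained = set(
            e.prune_non_trajectory(emb, bulk_products["meta"]["is_tumor"], k=15, radius=3, seed=0)
        )
        branch = bulk_products["truth"].samples["branch"]
        unrelated = set(branch.index[branch.str.startswith("unrelated")])
        trajectory = set(branch.index) - unrelated
        assert len(retained & unrelated) / len(unrelated) <= 0.10
        assert len(retained & trajectory) / len(trajectory) >= 0.90

    def test_no_tumor_is_error(self):
        names = ["a", "b", "c", "d", "e"]
        emb = e.Embedding(names, np.random.default_rng(11).normal(size=(5, 2)))
        with pytest.raises(ManifoldError):
            e.prune_non_trajectory(emb, pd.Series(False, index=names), k=2)
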