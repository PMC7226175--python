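"""Single-cell QC, normalization, cycle scoring, and score projection."""

import numpy as np
import pandas as pd
import pytest

import ewstraj as e
from ewstraj.containers import CountMatrix, NormalizedMatrix
from ewstraj.scproject import SCError, qc_metrics


class TestQC:
    def test_toy_metrics(self):
        cm = CountMatrix(["g1", "g2", "MT-g3"], ["c1"], np.array([[2], [0], [1]]))
        m = qc_metrics(cm)
        assert m.loc["c1", "n_umi"] == 3
        assert m.loc["c1", "n_genes"] == 2
        assert m.loc["c1", "pct_mito"] == pytest.approx(100 / 3)

    def test_clean_cells_mostly_retained(self):
        cfg = e.SimConfig(seed=6, n_genes=400)
        sc_cfg = e.SingleCellConfig(n_cells=400, damaged_fraction=0.0, seed=6)
        counts, _, truth = e.simulate_single_cells(cfg, sc_cfg)
        filtered, _ = e.qc_filter(counts)
        assert len(filtered.sample_ids) / len(counts.sample_ids) >= 0.95

    def test_damaged_cells_removed(self, sc_products):
        truth = sc_products["truth"].samples
        kept = set(sc_products["filtered"].sample_ids)
        damaged = set(truth.index[truth["damaged"]])
        removed_frac = 1 - len(kept & damaged) / len(damaged)
        assert removed_frac >= 0.90
        clean = set(truth.index[~truth["damaged"]])
        assert len(kept & clean) / len(clean) >= 0.95

    def test_missing_mito_tag_is_error(self):
        cm = CountMatrix(["g1", "g2"], ["c1", "c2"], np.array([[1, 2], [3, 4]]))
        with pytest.raises(SCError, match="mito"):
            e.qc_filter(cm)


class TestLognormScale:
    def test_constant_gene_scales_to_zero(self):
        counts = np.vstack([np.full(4, 5), np.arange(1, 5)])
        cm = CountMatrix(["g1", "g2"], [f"c{i}" for i in range(4)], counts)
        # note g1 is constant in counts but not after depth normalization;
        # use equal depths so it stays constant
        cm = CountMatrix(["g1", "g2"], [f"c{i}" for i in range(4)],
                         np.vstack([np.full(4, 5), np.full(4, 7)]))
        scaled = e.lognorm_scale(cm)
        assert np.allclose(scaled.values, 0.0)

    def test_per_gene_mean_zero(self, sc_products):
        scaled = sc_products["scaled"]
        unclipped = np.abs(scaled.values).max(axis=1) < 10  # clipping shifts the mean
        nonconst = scaled.values.std(axis=1) > 0
        sel = unclipped & nonconst
        assert sel.sum() > 100
        assert np.allclose(scaled.values[sel].mean(axis=1), 0.0, atol=1e-10)

    def test_hand_computed_four_cells(self):
        counts = np.array([[1, 0, 2, 4], [9, 10, 8, 6]])
        cm = CountMatrix(["g1", "g2"], [f"c{i}" for i in range(4)], counts)
        ln = e.lognorm(cm, target_sum=10)
        totals = counts.sum(axis=0)
        expected = np.log2(1 + counts / totals * 10)
        assert np.allclose(ln.values, expected)
        scaled = e.lognorm_scale(cm, target_sum=10)
        z = (expected - expected.mean(axis=1, keepdims=True)) / expected.std(axis=1, keepdims=True)
        assert np.allclose(scaled.values, z)

    def test_zero_total_cell_removed(self):
        counts = np.array([[1, 0], [2, 0]])
        cm = CountMatrix(["g1", "g2"], ["c1", "c2"], counts)
        with pytest.warns(UserWarning, match="zero-total"):
            ln = e.lognorm(cm)
        assert ln.sample_ids == ["c1"]


class TestCellCycle:
    def test_negative_scores_call_g1(self):
        # two cells: in the first, phase genes sit below the background
        # (negative module scores -> G1); in the second, above (cycling)
        values = np.zeros((60, 2))
        values[:10] = [-5.0, 5.0]    # S genes
        values[10:20] = [-4.0, 4.0]  # G2M genes
        norm = NormalizedMatrix(
            [f"g{i}" for i in range(60)], ["c_g1", "c_cycling"], values, "vst"
        )
        sets = {"S": {f"g{i}" for i in range(10)}, "G2M": {f"g{i}" for i in range(10, 20)}}
        cc = e.cell_cycle_score(norm, sets, n_bins=1, seed=1)
        assert cc.loc["c_g1", "S_score"] <= 0 and cc.loc["c_g1", "G2M_score"] <= 0
        assert cc.loc["c_g1", "phase"] == "G1"
        assert cc.loc["c_cycling", "phase"] == "S"

    def test_planted_g2m_cells_score_higher(self, sc_products):
        truth = sc_products["truth"]
        sets = e.phase_gene_sets(truth)
        cc = e.cell_cycle_score(
            sc_products["lognorm"], {"S": sets["S_PHASE"], "G2M": sets["G2M_PHASE"]}, seed=0
        )
        phase = truth.samples.loc[cc.index, "phase"]
        g2m = phase.index[phase == "G2M"]
        assert (cc.loc[g2m, "G2M_score"] > cc.loc[g2m, "S_score"]).mean() >= 0.9

    def test_invariant_to_cell_order(self, sc_products):
        truth = sc_products["truth"]
        sets = e.phase_gene_sets(truth)
        ln = sc_products["lognorm"]
        cc1 = e.cell_cycle_score(ln, {"S": sets["S_PHASE"], "G2M": sets["G2M_PHASE"]}, seed=2)
        perm = list(reversed(ln.sample_ids))
        cc2 = e.cell_cycle_score(
            ln.subset_samples(perm), {"S": sets["S_PHASE"], "G2M": sets["G2M_PHASE"]}, seed=2
        )
        assert np.allclose(cc1.loc[perm, "S_score"], cc2["S_score"])

    def test_missing_phase_genes_error(self, sc_products):
        with pytest.raises(SCError):
            e.cell_cycle_score(sc_products["lognorm"], {"S": {"nope"}, "G2M": {"nope2"}})


class TestProjection:
    def test_single_gene_score(self):
        counts = CountMatrix(["g1"], ["c1"], np.array([[3]]))
        scaled = NormalizedMatrix(["g1"], ["c1"], np.array([[2.0]]), "log-scaled")
        weights = pd.Series([-0.5], index=["g1"])
        res = e.project_phate1_score(scaled, counts, weights)
        assert res.loc["c1", "phate1_score"] == pytest.approx(-1.0)
        assert res.loc["c1", "n_genes_used"] == 1

    def test_all_zero_weights_flagged_missing(self):
        counts = CountMatrix(["g1", "g2"], ["c1"], np.array([[3], [1]]))
        scaled = NormalizedMatrix(["g1", "g2"], ["c1"], np.array([[2.0], [1.0]]), "log-scaled")
        weights = pd.Series([0.0, 0.0], index=["g1", "g2"])
        res = e.project_phate1_score(scaled, counts, weights)
        assert res.loc["c1", "missing"]
        assert np.isnan(res.loc["c1", "phate1_score"])

    def test_unexpressed_genes_excluded(self):
        counts = CountMatrix(["g1", "g2"], ["c1"], np.array([[0], [2]]))
        scaled = NormalizedMatrix(["g1", "g2"], ["c1"], np.array([[5.0], [1.0]]), "log-scaled")
        weights = pd.Series([1.0, 0.5], index=["g1", "g2"])
        res = e.project_phate1_score(scaled, counts, weights)
        assert res.loc["c1", "phate1_score"] == pytest.approx(0.5)

    def test_invariant_to_genes_absent_from_weights(self):
        rng = np.random.default_rng(3)
        counts_arr = rng.poisson(2, (6, 10))
        cm = CountMatrix([f"g{i}" for i in range(6)], [f"c{i}" for i in range(10)], counts_arr)
        scaled = NormalizedMatrix(cm.gene_ids, cm.sample_ids, rng.normal(size=(6, 10)), "log-scaled")
        weights = pd.Series([0.4, -0.2, 0.7], index=["g0", "g2", "g4"])
        full = e.project_phate1_score(scaled, cm, weights)
        sub_idx = np.array([0, 2, 4])
        sub = e.project_phate1_score(
            scaled.subset_genes(["g0", "g2", "g4"]), cm.subset_genes(sub_idx), weights
        )
        assert np.allclose(full["phate1_score"], sub["phate1_score"], equal_nan=True)

    def test_no_shared_genes_error(self):
        counts = CountMatrix(["g1"], ["c1"], np.array([[1]]))
        scaled = NormalizedMatrix(["g1"], ["c1"], np.array([[1.0]]), "log-scaled")
        with pytest.raises(SCError):
            e.project_phate1_score(scaled, counts, pd.Series([1.0], index=["other"]))


class TestClusterRanking:
    def test_single_cluster_trivial(self):
        scores = pd.DataFrame(
            {"phate1_score": [0.1, 0.2, 0.3]}, index=["c1", "c2", "c3"]
        )
        clusters = pd.Series([0, 0, 0], index=scores.index)
        res = e.rank_cell_clusters(scores, clusters)
        assert list(res.index) == [0]
        assert res.loc[0, "rank"] == 1

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        scores = pd.DataFrame(
            {"phate1_score": rng.normal(size=30)}, index=[f"c{i}" for i in range(30)]
        )
        clusters = pd.Series(rng.integers(0, 3, 30), index=scores.index)
        a = e.rank_cell_clusters(scores, clusters)
        relabeled = clusters.map({0: "x", 1: "y", 2: "z"})
        b = e.rank_cell_clusters(scores, relabeled)
        assert list(a["median_score"]) == list(b["median_score"])


class TestClusterMarkers:
    def test_positive_negative_disjoint_and_planted_recovery(self, sc_products, embedding_products):
        truth = sc_products["truth"]
        clusters = sc_products["clusters"]
        ln = sc_products["lognorm"]
        genes = truth.genes
        low_up = set(genes["beta"].sort_values().index[-100:])
        rng = np.random.default_rng(5)
        coll = e.GeneSetCollection(
            {"LOW_DOSAGE_UP": low_up,
             **{f"R{i}": set(rng.choice(genes.index, 100, replace=False)) for i in range(8)}}
        )
        res = e.cluster_markers_and_enrichment(ln, clusters, coll, min_log2fc=0.25, max_padj=0.05)
        sub = truth.samples.loc[ln.sample_ids, "subpop"]
        low_cluster = pd.crosstab(sub, clusters.reindex(ln.sample_ids)).loc["low_dosage"].idxmax()
        entry = res[low_cluster]
        assert not (entry["positive"] & entry["negative"])
        ora = entry["ora_positive"]
        assert ora.loc["LOW_DOSAGE_UP", "p_adj"] < 0.05
        # recovery of the truly shifted genes between subpopulations
        dz = abs(
            truth.samples.groupby(sub)["z"].mean().diff().iloc[-1]
        )
        true_de = set(genes.index[genes["beta"].abs() * dz > 1.0])
        found = entry["positive"] | entry["negative"]
        assert len(found & true_de) / len(true_de) >= 0.8

    def test_tiny_cluster_skipped(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=(10, 12))
        norm = NormalizedMatrix(
            [f"g{i}" for i in range(10)], [f"c{i}" for i in range(12)], values, "vst"
        )
        clusters = pd.Series([0] * 10 + [1] * 2, index=norm.sample_ids)
        coll = e.GeneSetCollection({"S": {"g1", "g2", "g3"}})
        with pytest.warns(UserWarning, match="skipped"):
            res = e.cluster_markers_and_enrichment(norm, clusters, coll)
        assert 1 not in res
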