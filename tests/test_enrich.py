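"""GSEA running sum, ORA hypergeometric, BH, curation, and comparisons."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ewstraj as e
from ewstraj.enrich import EnrichError, _es_batch, bh_adjust


def _ranking(n=20, seed=0):
    rng = np.random.default_rng(seed)
    scores = np.sort(rng.normal(size=n))[::-1]
    return pd.Series(scores, index=[f"g{i:02d}" for i in range(n)])


def brute_force_es(scores_sorted: np.ndarray, hit_mask: np.ndarray, p: float = 1.0) -> float:
    """Independent running-sum oracle: explicit loop over the ranked list."""
    w = np.abs(scores_sorted) ** p
    hit_total = w[hit_mask].sum()
    n_miss = (~hit_mask).sum()
    running, best = 0.0, 0.0
    for i in range(len(scores_sorted)):
        if hit_mask[i]:
            running += w[i] / hit_total
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


class TestGseaES:
    def test_top_block_scores_one(self):
        ranking = _ranking()
        coll = e.GeneSetCollection({"TOP": set(ranking.index[:5])})
        res = e.preranked_gsea(ranking, coll, n_perm=50, seed=0)
        assert res.loc["TOP", "es"] == pytest.approx(1.0)

    def test_whole_list_set_skipped(self):
        ranking = _ranking()
        coll = e.GeneSetCollection({"ALL": set(ranking.index)})
        res = e.preranked_gsea(ranking, coll, n_perm=50, seed=0, max_size=500)
        assert "ALL" not in res.index

    def test_small_set_skipped(self):
        ranking = _ranking()
        coll = e.GeneSetCollection({"TINY": set(ranking.index[:2])})
        res = e.preranked_gsea(ranking, coll, n_perm=50, seed=0, min_size=5)
        assert "TINY" not in res.index

    def test_es_matches_brute_force_oracle(self):
        ranking = _ranking(seed=3)
        rng = np.random.default_rng(4)
        scores_sorted = ranking.to_numpy()
        for trial in range(25):
            hits = rng.choice(20, 5, replace=False)
            mask = np.zeros(20, dtype=bool)
            mask[hits] = True
            ours = float(_es_batch(np.abs(scores_sorted), np.sort(hits)[None, :])[0])
            oracle = brute_force_es(scores_sorted, mask)
            assert ours == pytest.approx(oracle, abs=1e-12)

    def test_leading_edge_subset_of_set(self):
        ranking = _ranking(seed=5)
        rng = np.random.default_rng(6)
        sets = {
            f"S{i}": set(rng.choice(ranking.index, 6, replace=False)) for i in range(5)
        }
        coll = e.GeneSetCollection(sets)
        res = e.preranked_gsea(ranking, coll, n_perm=100, seed=0)
        for name, row in res.iterrows():
            le = set(row["leading_edge"].split(","))
            assert le <= coll[name]


class TestGseaPermutation:
    def test_permutation_p_within_ci_of_exhaustive(self):
        """Permutation p agrees with exhaustive C(20,5) enumeration."""
        ranking = _ranking(seed=7)
        w = np.abs(ranking.to_numpy())
        rng = np.random.default_rng(8)
        hits = np.sort(rng.choice(20, 5, replace=False))
        es_obs = float(_es_batch(w, hits[None, :])[0])

        all_sets = np.array(list(itertools.combinations(range(20), 5)))
        es_all = _es_batch(w, all_sets)
        same = es_all >= 0 if es_obs >= 0 else es_all < 0
        p_exact = (np.abs(es_all[same]) >= abs(es_obs) - 1e-15).sum() / same.sum()

        coll = e.GeneSetCollection({"Q": {f"g{i:02d}" for i in hits}})
        res = e.preranked_gsea(ranking, coll, n_perm=10_000, seed=9)
        p_perm = res.loc["Q", "p"]
        half_width = 1.96 * math.sqrt(p_exact * (1 - p_exact) / 10_000) + 2 / 10_001
        assert abs(p_perm - p_exact) <= half_width

    def test_deterministic_given_seed(self):
        ranking = _ranking(seed=10)
        coll = e.GeneSetCollection({"Q": set(ranking.index[3:9])})
        a = e.preranked_gsea(ranking, coll, n_perm=200, seed=11)
        b = e.preranked_gsea(ranking, coll, n_perm=200, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_duplicate_gene_ids_error(self):
        ranking = pd.Series([1.0, 2.0], index=["g", "g"])
        with pytest.raises(EnrichError):
            e.preranked_gsea(ranking, e.GeneSetCollection({"S": {"g"}}))


class TestOra:
    def test_full_overlap_closed_form(self):
        universe = {f"g{i}" for i in range(20)}
        query = {f"g{i}" for i in range(5)}
        coll = e.GeneSetCollection({"S": query})
        res = e.ora_hypergeometric(query, universe, coll)
        assert res.loc["S", "p"] == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_zero_overlap_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        coll = e.GeneSetCollection({"S": {f"g{i}" for i in range(10, 15)}})
        res = e.ora_hypergeometric({f"g{i}" for i in range(5)}, universe, coll)
        assert res.loc["S", "p"] == pytest.approx(1.0)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(12)
        for trial in range(20):
            N = int(rng.integers(20, 60))
            K = int(rng.integers(3, N // 2))
            n = int(rng.integers(3, N // 2))
            universe = {f"g{i}" for i in range(N)}
            set_genes = set(rng.choice(sorted(universe), K, replace=False))
            query = set(rng.choice(sorted(universe), n, replace=False))
            k = len(query & set_genes)
            res = e.ora_hypergeometric(query, universe, e.GeneSetCollection({"S": set_genes}))
            # direct summation of the hypergeometric upper tail
            p_oracle = sum(
                math.comb(K, j) * math.comb(N - K, n - j) / math.comb(N, n)
                for j in range(k, min(K, n) + 1)
            )
            assert res.loc["S", "p"] == pytest.approx(p_oracle, abs=1e-12)

    def test_empty_query_error(self):
        with pytest.raises(EnrichError):
            e.ora_hypergeometric(set(), {"g"}, e.GeneSetCollection({"S": {"g"}}))

    def test_query_outside_universe_error(self):
        with pytest.raises(EnrichError):
            e.ora_hypergeometric({"x"}, {"g"}, e.GeneSetCollection({"S": {"g"}}))


class TestBH:
    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(size=30)
        assert np.allclose(bh_adjust(p), stats.false_discovery_control(p, method="bh"))

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(14)
        p = rng.uniform(size=25)
        adj = bh_adjust(p)
        assert np.all(adj <= 1.0)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestCompare:
    def _res(self, names, sig):
        p = np.where(np.isin(names, sig), 1e-6, 0.9)
        return pd.DataFrame({"p": p, "p_adj": p}, index=names)

    def test_identical_results_full_overlap(self):
        names = [f"S{i}" for i in range(30)]
        a = self._res(names, names[:6])
        rep = e.compare_enrichments(a, a.copy(), alpha=0.05)
        assert rep["n_shared"] == 6
        # minimal attainable overlap p for this configuration: 1 / C(30, 6)
        assert rep["p_overlap"] == pytest.approx(1 / math.comb(30, 6), rel=1e-9)

    def test_disjoint_significant_sets(self):
        names = [f"S{i}" for i in range(30)]
        a = self._res(names, names[:5])
        b = self._res(names, names[5:10])
        rep = e.compare_enrichments(a, b, alpha=0.05)
        assert rep["n_shared"] == 0
        assert rep["p_overlap"] >= 0.5

    def test_different_collections_error(self):
        a = self._res(["S1", "S2"], ["S1"])
        b = self._res(["S1", "S3"], ["S1"])
        with pytest.raises(EnrichError):
            e.compare_enrichments(a, b)


class TestMetaCategories:
    def test_multi_assignment_and_uncategorized(self):
        counts = e.assign_meta_categories(
            ["CELL_CYCLE_G2M", "DNA_REPAIR_CYCLE", "SPLICEOSOME"],
            {"cycle": "CYCLE", "repair": "REPAIR"},
        )
        assert counts == {"cycle": 2, "repair": 1, "uncategorized": 1}

    def test_empty_dictionary_all_uncategorized(self):
        counts = e.assign_meta_categories(["A", "B"], {})
        assert counts == {"uncategorized": 2}

    def test_hand_evaluated_fixture(self):
        names = [f"SET_{tag}_{i}" for i, tag in enumerate(
            ["RNA", "RNA", "DNA", "CYCLE", "RNA_CYCLE", "MISC", "DNA", "CYCLE", "MISC", "RNA"]
        )]
        counts, assignments = e.assign_meta_categories(
            names, {"rna": "RNA", "dna": "DNA", "cycle": "CYCLE"}, return_assignments=True
        )
        assert counts == {"rna": 4, "dna": 2, "cycle": 3, "uncategorized": 2}
        assert assignments[names[4]] == ["rna", "cycle"]


class TestCuration:
    def _source(self):
        return e.GeneSetCollection(
            {
                "EWING_UP": {"A", "B", "C"},
                "EWING_DOWN": {"D"},
                "OTHER_PATHWAY": {"E"},
                "EWSR1_TARGETS": {"B", "C", "D"},
            }
        )

    def test_regex_include_and_censor(self):
        out = e.curate_collection(
            self._source(), include_regex="EWING|EWSR1", censor_names=["EWING_DOWN"]
        )
        assert set(out.names()) == {"EWING_UP", "EWSR1_TARGETS"}
        assert any("censored:EWING_DOWN" in line for line in out.provenance)

    def test_include_matching_nothing_gives_empty(self):
        out = e.curate_collection(self._source(), include_regex="ZZZ")
        assert len(out) == 0

    def test_intersection_derived_set(self):
        out = e.curate_collection(
            self._source(),
            derived_ops=[
                {"name": "NEW", "op": "intersection", "sets": ["EWING_UP", "EWSR1_TARGETS"]}
            ],
        )
        assert out["NEW"] == {"B", "C"}

    def test_missing_reference_error(self):
        with pytest.raises(EnrichError):
            e.curate_collection(
                self._source(),
                derived_ops=[{"name": "X", "op": "union", "sets": ["NOPE"]}],
            )
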