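"""High-level analysis recipes chaining the pipeline stages in memory.

These functions run the same stage sequence as :mod:`ewstraj.pipeline` but
return the in-memory products, which makes them convenient for recovery
studies on simulated data: simulate, analyze, and score the result against
the generator's ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import (
    CountMatrix,
    GeneSetCollection,
    embed_trajectory,
    filter_genes,
    gene_axis_correlation,
    knn_graph,
    louvain,
    marker_score,
    median_by_ratio_normalize,
    orient_axis,
    pca,
    preranked_gsea,
    prune_non_trajectory,
    select_variable_genes,
    simulate_bulk_compendium,
    simulate_gene_sets,
    simulate_knockdown,
    size_factors_median_ratio,
    vst,
    wilcoxon_markers,
)
from .markers import select_top_clusters
from .synth import SimConfig


def bulk_chain(
    cfg: SimConfig,
    marker_min_log2fc: float = 0.58,
    marker_max_padj: float = 0.05,
    n_variable_genes: int = 1000,
    n_pcs: int = 100,
    knn_k: int = 20,
    embed_k: int = 15,
    embed_decay: float = 10.0,
    embed_t: int = 40,
    prune_radius: int = 3,
    anchor: str = "mesoderm",
) -> dict:
    """Simulate a compendium and run the bulk stages end to end.

    Filtering, normalization, clustering, marker discovery, marker-score
    cluster selection, trajectory embedding with pruning and orientation,
    and signed-R^2 gene scoring. The marker adjusted-p threshold defaults to
    0.05 (Bonferroni), appropriate for simulation-scale cohorts.
    """
    counts, meta, truth = simulate_bulk_compendium(cfg)
    filtered = filter_genes(counts, 0.10)
    factors = size_factors_median_ratio(filtered)
    vst_mat = vst(filtered, factors)
    mbr = median_by_ratio_normalize(filtered)
    var_genes = select_variable_genes(vst_mat, min(n_variable_genes, len(vst_mat.gene_ids)))
    pca_scores, _ = pca(vst_mat.subset_genes(var_genes), min(n_pcs, len(vst_mat.sample_ids) - 1))
    clusters = louvain(knn_graph(pca_scores, knn_k), 1.0, seed=cfg.seed)
    labels = pd.Series(np.where(meta["is_tumor"], "tumor", meta["tissue"]), index=meta.index)
    marker_table = wilcoxon_markers(
        vst_mat, labels.reindex(vst_mat.sample_ids), "tumor", marker_min_log2fc, marker_max_padj
    )
    marker_genes = list(marker_table.index[marker_table["passes"]])
    scores = marker_score(vst_mat, marker_genes)
    cluster_medians = scores.groupby(clusters.reindex(scores.index)).median()
    selected = [
        s for s in scores.index if clusters[s] in set(select_top_clusters(cluster_medians))
    ]
    emb3 = embed_trajectory(
        pca_scores.loc[selected], k=min(embed_k, len(selected) - 1),
        decay=embed_decay, t=embed_t, n_dims=3,
    )
    retained = prune_non_trajectory(
        emb3, meta["is_tumor"], k=min(embed_k, len(selected) - 1),
        radius=prune_radius, seed=cfg.seed,
    )
    embedding = embed_trajectory(
        pca_scores.loc[retained], k=min(embed_k, len(retained) - 1),
        decay=embed_decay, t=embed_t, n_dims=3,
    )
    embedding = orient_axis(embedding, meta["tissue"], anchor)
    traj_scores = gene_axis_correlation(mbr, embedding, retained, "all")
    normals = [s for s in retained if not bool(meta.loc[s, "is_tumor"])]
    traj_scores_normals = (
        gene_axis_correlation(mbr, embedding, normals, "normals-only")
        if len(normals) >= 3 else None
    )
    return {
        "cfg": cfg, "counts": counts, "meta": meta, "truth": truth,
        "filtered": filtered, "factors": factors, "vst": vst_mat, "mbr": mbr,
        "pca": pca_scores, "clusters": clusters, "labels": labels,
        "marker_table": marker_table, "marker_genes": marker_genes,
        "marker_scores": scores, "selected": selected, "emb3": emb3,
        "retained": retained, "embedding": embedding,
        "traj_scores": traj_scores, "traj_scores_normals": traj_scores_normals,
    }


def trajectory_recovery(chain: dict) -> float:
    """|Spearman rho| between oriented axis 1 and true pseudotime z over the
    retained on-trajectory samples."""
    truth = chain["truth"]
    on_traj = [
        s for s in chain["retained"]
        if not str(truth.samples.loc[s, "branch"]).startswith("unrelated")
    ]
    rho = spearmanr(
        chain["embedding"].axis1.loc[on_traj], truth.samples.loc[on_traj, "z"]
    )[0]
    return float(abs(rho))


def marker_recovery(seed: int) -> dict:
    """Tumor-marker sensitivity/FDR at effect 1.5 log2, 100 tumor vs 300 rest."""
    # rest of the cohort is context-rich (the tumor's developmental context
    # is well represented), so marker detection reflects the marker effect
    # rather than the tumor group's position on the trajectory
    cfg = SimConfig(
        seed=seed, n_tumor=100, n_pluripotent=75, n_neuroectoderm=75, n_mesoderm=75,
        n_unrelated_groups=1, n_per_unrelated=75, marker_effect_log2=1.5,
    )
    counts, meta, truth = simulate_bulk_compendium(cfg)
    filtered = filter_genes(counts, 0.10)
    vst_mat = vst(filtered, size_factors_median_ratio(filtered))
    labels = pd.Series(np.where(meta["is_tumor"], "tumor", meta["tissue"]), index=meta.index)
    table = wilcoxon_markers(vst_mat, labels.reindex(vst_mat.sample_ids), "tumor", 0.58, 0.05)
    found = set(table.index[table["passes"]])
    true_markers = set(truth.genes.index[truth.genes["is_marker"]])
    detectable = true_markers & set(filtered.gene_ids)
    sensitivity = len(found & true_markers) / len(detectable)
    fdr = len(found - true_markers) / max(len(found), 1)
    return {"sensitivity": sensitivity, "fdr": fdr, "n_found": len(found),
            "n_true_detectable": len(detectable)}


def knockdown_shift(chain: dict, n_pairs: int = 6, dosage_drop: float = 0.8) -> dict:
    """Embed paired knockdown samples jointly with the compendium and test the
    axis-1 shift (one-tailed: knockdown arm expected higher)."""
    from .trajscore import intervention_shift_test

    cfg, truth, meta = chain["cfg"], chain["truth"], chain["meta"]
    kd_counts, kd_meta, _ = simulate_knockdown(
        cfg, n_pairs=n_pairs, dosage_drop=dosage_drop, latents=truth.genes
    )
    counts = chain["counts"]
    joint = CountMatrix(
        list(counts.gene_ids),
        counts.sample_ids + kd_counts.sample_ids,
        np.hstack([counts.dense(), kd_counts.dense()]),
    )
    filtered = filter_genes(joint, 0.10)
    vst_mat = vst(filtered, size_factors_median_ratio(filtered))
    var_genes = select_variable_genes(vst_mat, min(1000, len(vst_mat.gene_ids)))
    pca_scores, _ = pca(vst_mat.subset_genes(var_genes), min(100, len(vst_mat.sample_ids) - 1))
    on_traj = [
        s for s in counts.sample_ids
        if not str(truth.samples.loc[s, "branch"]).startswith("unrelated")
    ]
    emb = embed_trajectory(
        pca_scores.loc[on_traj + kd_counts.sample_ids], k=15, decay=10.0, t=40, n_dims=3
    )
    emb = orient_axis(emb, meta["tissue"], "mesoderm")
    return intervention_shift_test(emb, kd_meta, tail="greater")


def gene_score_recovery(chain: dict) -> float:
    """Spearman rho between signed-R^2 and the true trajectory loadings."""
    truth = chain["truth"]
    scores = chain["traj_scores"]
    traj_genes = [
        g for g in scores.index if truth.genes.loc[g, "is_trajectory"]
    ]
    sub = scores.loc[traj_genes]
    ok = sub["defined"]
    return float(spearmanr(sub.loc[ok, "signed_r2"], truth.genes.loc[sub.index[ok], "beta"])[0])


def gsea_planted_recovery(chain: dict, n_sets: int = 40, planted_fraction: float = 0.25,
                          n_perm: int = 2000, seed: int = 0) -> dict:
    """GSEA sensitivity for planted negative-loading sets at BH < 0.05."""
    collection, set_truth = simulate_gene_sets(
        chain["truth"], n_sets=n_sets, planted_fraction=planted_fraction, seed=seed
    )
    ranking = chain["traj_scores"].loc[chain["traj_scores"]["defined"], "signed_r2"]
    res = preranked_gsea(ranking, collection, n_perm=n_perm, seed=seed)
    merged = res.join(set_truth)
    planted_neg = merged[(merged["planted"]) & (merged["direction"] == -1)]
    planted_all = merged[merged["planted"]]
    return {
        "sensitivity_negative": float((planted_neg["p_adj"] < 0.05).mean()),
        "sensitivity_all": float((planted_all["p_adj"] < 0.05).mean()),
        "es_sign_correct": float(
            (np.sign(planted_all["es"]) == planted_all["direction"]).mean()
        ),
        "results": res,
    }


def gsea_null_calibration(chain: dict, n_sets: int = 200, set_size: int = 50,
                          n_perm: int = 2000, seed: int = 0) -> float:
    """Fraction of random (null) sets rejected at raw p < 0.05."""
    ranking = chain["traj_scores"].loc[chain["traj_scores"]["defined"], "signed_r2"]
    rng = np.random.default_rng(seed)
    sets = {
        f"NULL_{i:03d}": set(rng.choice(ranking.index.to_numpy(), set_size, replace=False))
        for i in range(n_sets)
    }
    res = preranked_gsea(ranking, GeneSetCollection(sets), n_perm=n_perm, seed=seed)
    return float((res["p"] < 0.05).mean())


def single_cell_projection(cfg: SimConfig, traj_scores: pd.DataFrame, seed: int = 0) -> dict:
    """Simulate single cells, QC, cluster, project bulk weights, rank clusters,
    and ORA the top cluster's positive markers against a planted collection."""
    from . import (
        GeneSetCollection as GSC,
        cluster_markers_and_enrichment,
        lognorm,
        lognorm_scale,
        project_phate1_score,
        qc_filter,
        rank_cell_clusters,
        simulate_single_cells,
    )

    sc_counts, _, sc_truth = simulate_single_cells(cfg)
    filtered, _ = qc_filter(sc_counts)
    scaled = lognorm_scale(filtered)
    ln = lognorm(filtered)
    pcs, _ = pca(scaled, min(50, len(scaled.sample_ids) - 1))
    clusters = louvain(knn_graph(pcs, 20), 1.0, seed=seed)
    cell_scores = project_phate1_score(scaled, filtered, traj_scores)
    ranking = rank_cell_clusters(cell_scores, clusters)
    dosage = sc_truth.samples.loc[cell_scores.index, "dosage"]
    rho = float(spearmanr(cell_scores["phate1_score"], dosage)[0])

    cluster_dosage = dosage.groupby(clusters.reindex(dosage.index)).median()
    low_cluster = cluster_dosage.idxmin()
    top_is_low = ranking.index[0] == low_cluster

    genes = sc_truth.genes
    planted = set(genes["beta"].sort_values().index[-100:])  # up when dosage is low
    rng = np.random.default_rng(seed + 1)
    collection = GSC(
        {"PLANTED_LOW_DOSAGE_UP": planted,
         **{f"NULL_{i}": set(rng.choice(genes.index.to_numpy(), 100, replace=False))
            for i in range(9)}}
    )
    markers = cluster_markers_and_enrichment(
        ln, clusters, collection, min_log2fc=0.25, max_padj=0.05
    )
    ora = markers[low_cluster]["ora_positive"]
    planted_padj = float(ora.loc["PLANTED_LOW_DOSAGE_UP", "p_adj"]) if ora is not None else 1.0
    return {
        "score_dosage_spearman": rho,
        "low_dosage_cluster_ranks_first": bool(top_is_low),
        "planted_set_padj": planted_padj,
        "cluster_ranking": ranking,
        "truth": sc_truth,
        "cell_scores": cell_scores,
    }
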