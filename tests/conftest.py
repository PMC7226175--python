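"""Shared fixtures: one default bulk simulation and one single-cell
simulation, carried through the pipeline stages once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ewstraj as e
from ewstraj.markers import select_top_clusters

BULK_SEED = 3


@pytest.fixture(scope="session")
def bulk_sim():
    cfg = e.SimConfig(seed=BULK_SEED)
    counts, meta, truth = e.simulate_bulk_compendium(cfg)
    return {"cfg": cfg, "counts": counts, "meta": meta, "truth": truth}


@pytest.fixture(scope="session")
def bulk_products(bulk_sim):
    counts, meta, truth = bulk_sim["counts"], bulk_sim["meta"], bulk_sim["truth"]
    filtered = e.filter_genes(counts, 0.10)
    factors = e.size_factors_median_ratio(filtered)
    vst = e.vst(filtered, factors)
    mbr = e.median_by_ratio_normalize(filtered)
    var_genes = e.select_variable_genes(vst, min(1000, len(vst.gene_ids)))
    pca_scores, evr = e.pca(vst.subset_genes(var_genes), 100)
    graph = e.knn_graph(pca_scores, 20)
    clusters = e.louvain(graph, 1.0, seed=0)
    labels = pd.Series(
        np.where(meta["is_tumor"], "tumor", meta["tissue"]), index=meta.index
    )
    # marker p threshold appropriate to a ~400-sample cohort
    marker_table = e.wilcoxon_markers(vst, labels.reindex(vst.sample_ids), "tumor", 0.58, 0.05)
    marker_genes = list(marker_table.index[marker_table["passes"]])
    marker_scores = e.marker_score(vst, marker_genes)
    cluster_medians = marker_scores.groupby(clusters.reindex(marker_scores.index)).median()
    top_clusters = set(select_top_clusters(cluster_medians))
    selected = [s for s in marker_scores.index if clusters[s] in top_clusters]
    return {
        **bulk_sim,
        "filtered": filtered,
        "factors": factors,
        "vst": vst,
        "mbr": mbr,
        "pca": pca_scores,
        "clusters": clusters,
        "labels": labels,
        "marker_table": marker_table,
        "marker_genes": marker_genes,
        "marker_scores": marker_scores,
        "selected": selected,
    }


@pytest.fixture(scope="session")
def embedding_products(bulk_products):
    meta, truth = bulk_products["meta"], bulk_products["truth"]
    pca_scores = bulk_products["pca"]
    selected = bulk_products["selected"]
    emb3 = e.embed_trajectory(pca_scores.loc[selected], k=15, decay=10.0, t=40, n_dims=3)
    retained = e.prune_non_trajectory(emb3, meta["is_tumor"], k=15, radius=3, seed=0)
    final = e.embed_trajectory(pca_scores.loc[retained], k=15, decay=10.0, t=40, n_dims=3)
    final = e.orient_axis(final, meta["tissue"], "mesoderm")
    traj_all = e.gene_axis_correlation(bulk_products["mbr"], final, retained, "all")
    normals = [s for s in retained if not bool(meta.loc[s, "is_tumor"])]
    tumors = [s for s in retained if bool(meta.loc[s, "is_tumor"])]
    traj_normals = e.gene_axis_correlation(bulk_products["mbr"], final, normals, "normals-only")
    traj_ewing = (
        e.gene_axis_correlation(bulk_products["mbr"], final, tumors, "ewing-only")
        if len(tumors) >= 3
        else None
    )
    return {
        **bulk_products,
        "emb3": emb3,
        "retained": retained,
        "embedding": final,
        "traj_scores": traj_all,
        "traj_scores_normals": traj_normals,
        "traj_scores_ewing": traj_ewing,
    }


@pytest.fixture(scope="session")
def sc_sim():
    cfg = e.SimConfig(seed=BULK_SEED)
    counts, meta, truth = e.simulate_single_cells(cfg)
    return {"cfg": cfg, "counts": counts, "meta": meta, "truth": truth}


@pytest.fixture(scope="session")
def sc_products(sc_sim):
    counts, truth = sc_sim["counts"], sc_sim["truth"]
    filtered, qc = e.qc_filter(counts)
    scaled = e.lognorm_scale(filtered)
    ln = e.lognorm(filtered)
    pcs, _ = e.pca(scaled, 50)
    clusters = e.louvain(e.knn_graph(pcs, 20), 1.0, seed=0)
    return {
        **sc_sim,
        "filtered": filtered,
        "qc": qc,
        "scaled": scaled,
        "lognorm": ln,
        "clusters": clusters,
    }
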