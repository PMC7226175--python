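"""End-to-end pipeline: chains the analysis stages and writes a run manifest.

Stage order: filter -> normalize -> cluster -> marker-score -> embed ->
trajectory-score -> enrich -> single-cell project. Every intermediate is
written as TSV under the output directory; the JSON manifest records the
seed, a hash of the configuration, and per-stage status/timings. Stages
whose inputs were not provided (gene sets, single cells) are recorded as
skipped. Any stage failure aborts the run with the stage name and cause.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from . import manifold, markers, normalize, scproject, trajscore
from .config import PipelineConfig, stream_rng
from .containers import CountMatrix, GeneSetCollection
from .enrich import preranked_gsea

log = logging.getLogger("ewstraj")

STAGES = [
    "filter",
    "normalize",
    "cluster",
    "marker-score",
    "embed",
    "trajectory-score",
    "enrich",
    "single-cell-project",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    config: PipelineConfig,
    inputs: dict,
    outdir: str | Path,
) -> dict:
    """Run the bulk (and optionally single-cell) analysis end to end.

    ``inputs`` keys: ``counts`` (path), ``counts_format`` ("tsv-dense" or
    "mtx-triplet"), ``meta`` (path), optional ``gmt`` (path), optional
    ``sc_counts`` (mtx-triplet directory), optional ``phase_gmt`` (path).
    Returns the manifest dict (also written to ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "stages": [],
    }
    state: dict = {}

    def _stage(name: str, fn, skip_reason: str | None = None):
        entry = {"name": name}
        if skip_reason is not None:
            entry.update(status="skipped", reason=skip_reason, seconds=0.0)
            manifest["stages"].append(entry)
            log.info("stage %-20s skipped (%s)", name, skip_reason)
            return
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(name, exc) from exc
        entry.update(status="completed", seconds=round(time.perf_counter() - t0, 3))
        manifest["stages"].append(entry)
        log.info("stage %-20s done in %.2fs", name, entry["seconds"])

    # ---- filter ---------------------------------------------------------
    def do_filter():
        counts = eio.read_counts(inputs["counts"], inputs.get("counts_format", "tsv-dense"))
        meta = eio.read_sample_meta(inputs["meta"])
        filtered = normalize.filter_genes(counts, config.max_zero_fraction)
        state["counts"] = filtered
        state["meta"] = meta
        eio.write_counts(filtered, outdir / "counts_filtered.tsv")

    _stage("filter", do_filter)

    # ---- normalize ------------------------------------------------------
    def do_normalize():
        factors = normalize.size_factors_median_ratio(state["counts"])
        state["vst"] = normalize.vst(state["counts"], factors)
        state["mbr"] = normalize.median_by_ratio_normalize(state["counts"])
        factors.to_frame().to_csv(outdir / "size_factors.tsv", sep="\t")
        eio.write_normalized(state["vst"], outdir / "vst.tsv")

    _stage("normalize", do_normalize)

    # ---- cluster --------------------------------------------------------
    def do_cluster():
        n_var = min(config.n_variable_genes, len(state["vst"].gene_ids))
        var_genes = normalize.select_variable_genes(state["vst"], n_var)
        state["vst_var"] = state["vst"].subset_genes(var_genes)
        scores, evr = manifold.pca(state["vst_var"], config.n_pcs)
        state["pca"] = scores
        graph = manifold.knn_graph(scores, config.knn_k)
        clusters = manifold.louvain(
            graph, config.louvain_resolution, seed=int(stream_rng(config.seed, "louvain").integers(2**31))
        )
        state["clusters"] = clusters
        scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
        clusters.to_frame().to_csv(outdir / "clusters.tsv", sep="\t")

    _stage("cluster", do_cluster)

    # ---- marker-score ---------------------------------------------------
    def do_markers():
        meta = state["meta"]
        labels = pd.Series(
            np.where(meta["is_tumor"], "tumor", meta["tissue"]), index=meta.index
        ).reindex(state["vst"].sample_ids)
        table = markers.wilcoxon_markers(
            state["vst"], labels, "tumor", config.min_log2fc, config.max_padj
        )
        marker_genes = list(table.index[table["passes"]])
        state["marker_table"] = table
        state["marker_genes"] = marker_genes
        score = markers.marker_score(state["vst"], marker_genes)
        state["marker_scores"] = score
        ranking = markers.rank_groups(score, state["clusters"].reindex(score.index))
        state["cluster_ranking"] = ranking
        comp = markers.composition_enrichment(
            labels, state["clusters"].reindex(labels.index)
        )
        table.to_csv(outdir / "marker_table.tsv", sep="\t")
        score.to_frame().to_csv(outdir / "marker_scores.tsv", sep="\t")
        ranking.table.to_csv(outdir / "cluster_ranking.tsv", sep="\t")
        comp.to_csv(outdir / "composition_enrichment.tsv", sep="\t")

    _stage("marker-score", do_markers)

    # ---- embed ----------------------------------------------------------
    def do_embed():
        clusters = state["clusters"]
        score = state["marker_scores"]
        cluster_med = score.groupby(clusters.reindex(score.index)).median()
        top = set(markers.select_top_clusters(cluster_med))
        selected = [s for s in score.index if clusters[s] in top]
        state["selected_samples"] = selected
        sub_scores = state["pca"].loc[selected]
        emb3 = manifold.embed_trajectory(
            sub_scores,
            k=min(config.embed_k, len(selected) - 1),
            decay=config.embed_decay,
            t=config.embed_t,
            n_dims=3,
        )
        is_tumor = state["meta"]["is_tumor"]
        retained = manifold.prune_non_trajectory(
            emb3,
            is_tumor,
            k=min(config.embed_k, len(selected) - 1),
            radius=config.prune_radius,
            seed=int(stream_rng(config.seed, "prune").integers(2**31)),
        )
        final = manifold.embed_trajectory(
            state["pca"].loc[retained],
            k=min(config.embed_k, len(retained) - 1),
            decay=config.embed_decay,
            t=config.embed_t,
            n_dims=config.embed_n_dims,
        )
        tissue = state["meta"]["tissue"]
        anchor = getattr(config, "anchor_group", "mesoderm")
        if (tissue.reindex(retained) == anchor).any():
            final = manifold.orient_axis(final, tissue, anchor)
        state["embedding"] = final
        state["retained"] = retained
        eio.write_embedding(final, outdir / "embedding.tsv")
        pd.Series(retained, name="sample_id").to_csv(outdir / "retained_samples.tsv", sep="\t", index=False)

    _stage("embed", do_embed)

    # ---- trajectory-score ----------------------------------------------
    def do_trajscore():
        emb = state["embedding"]
        meta = state["meta"]
        embedded = list(emb.sample_ids)
        tumors = [s for s in embedded if bool(meta.loc[s, "is_tumor"])]
        normals = [s for s in embedded if not bool(meta.loc[s, "is_tumor"])]
        scores_all = trajscore.gene_axis_correlation(state["mbr"], emb, embedded, "all")
        state["traj_scores"] = scores_all
        scores_all.to_csv(outdir / "trajectory_scores.tsv", sep="\t")
        if len(normals) >= 3:
            scores_norm = trajscore.gene_axis_correlation(state["mbr"], emb, normals, "normals-only")
            scores_norm.to_csv(outdir / "trajectory_scores_normals.tsv", sep="\t")
            low_markers = trajscore.threshold_markers(scores_norm, -0.2, "below")
            state["phate1_low_markers"] = low_markers
            pd.Series(sorted(low_markers), name="gene_id").to_csv(
                outdir / "phate1_low_markers.tsv", sep="\t", index=False
            )
        if len(tumors) >= 3:
            scores_ews = trajscore.gene_axis_correlation(state["mbr"], emb, tumors, "ewing-only")
            state["traj_scores_ewing"] = scores_ews
            scores_ews.to_csv(outdir / "trajectory_scores_ewing.tsv", sep="\t")

    _stage("trajectory-score", do_trajscore)

    # ---- enrich ---------------------------------------------------------
    if inputs.get("gmt"):
        def do_enrich():
            collection = eio.read_gmt(inputs["gmt"])
            ranking = state["traj_scores"].loc[
                state["traj_scores"]["defined"], "signed_r2"
            ]
            res = preranked_gsea(
                ranking,
                collection,
                n_perm=config.gsea_n_perm,
                weight_p=config.gsea_weight_p,
                min_size=config.gsea_min_size,
                max_size=config.gsea_max_size,
                seed=int(stream_rng(config.seed, "gsea").integers(2**31)),
            )
            state["gsea"] = res
            res.to_csv(outdir / "gsea_results.tsv", sep="\t")

        _stage("enrich", do_enrich)
    else:
        _stage("enrich", None, skip_reason="no gene set collection provided")

    # ---- single-cell project -------------------------------------------
    if inputs.get("sc_counts"):
        def do_sc():
            sc_counts = eio.read_counts(inputs["sc_counts"], "mtx-triplet")
            filtered, qc = scproject.qc_filter(sc_counts, nmads=config.qc_nmads)
            scaled = scproject.lognorm_scale(filtered, config.sc_target_sum, config.sc_scale_clip)
            ln = scproject.lognorm(filtered, config.sc_target_sum)
            scores_pca, _ = manifold.pca(scaled, min(50, len(scaled.sample_ids) - 1))
            graph = manifold.knn_graph(scores_pca, min(config.knn_k, len(scaled.sample_ids) - 1))
            clusters = manifold.louvain(
                graph, config.louvain_resolution,
                seed=int(stream_rng(config.seed, "sc-louvain").integers(2**31)),
            )
            cell_scores = scproject.project_phate1_score(scaled, filtered, state["traj_scores"])
            ranking = scproject.rank_cell_clusters(cell_scores, clusters)
            qc.to_csv(outdir / "sc_qc_metrics.tsv", sep="\t")
            clusters.to_frame().to_csv(outdir / "sc_clusters.tsv", sep="\t")
            cell_scores.to_csv(outdir / "sc_phate1_scores.tsv", sep="\t")
            ranking.to_csv(outdir / "sc_cluster_ranking.tsv", sep="\t")
            if inputs.get("phase_gmt"):
                phase_coll = eio.read_gmt(inputs["phase_gmt"])
                phase_sets = {
                    "S": phase_coll["S_PHASE"], "G2M": phase_coll["G2M_PHASE"]
                }
                cc = scproject.cell_cycle_score(
                    ln, phase_sets,
                    seed=int(stream_rng(config.seed, "cell-cycle").integers(2**31)),
                )
                cc.to_csv(outdir / "sc_cell_cycle.tsv", sep="\t")
            state["sc_cluster_ranking"] = ranking

        _stage("single-cell-project", do_sc)
    else:
        _stage("single-cell-project", None, skip_reason="no single-cell counts provided")

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
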