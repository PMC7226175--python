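"""Single-cell QC, normalization, cell-cycle scoring, and trajectory-score
projection.

The projection step transfers the bulk trajectory signature onto cells: each
cell's scaled expression values are multiplied by the per-gene signed-R^2
trajectory weights, and the cell's score is the median over the genes it
actually expresses (raw count > 0) that carry a defined, non-zero weight.
High fusion dosage corresponds to a low (pluripotent/neuroectodermal-like)
score, low dosage to a high (mesodermal-like) score.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .containers import CountMatrix, NormalizedMatrix
from .markers import wilcoxon_markers
from .enrich import ora_hypergeometric

log = logging.getLogger("ewstraj")


class SCError(ValueError):
    pass

_MAD_SCALE = 1.4826  # consistency with the normal distribution


def qc_metrics(counts: CountMatrix, mito_prefix: str = "MT-") -> pd.DataFrame:
    dense = counts.dense()
    mito = np.array([g.startswith(mito_prefix) for g in counts.gene_ids])
    n_umi = dense.sum(axis=0)
    n_genes = (dense > 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(n_umi > 0, 100.0 * dense[mito].sum(axis=0) / n_umi, 0.0)
    return pd.DataFrame(
        {"n_umi": n_umi, "n_genes": n_genes, "pct_mito": pct_mito},
        index=pd.Index(counts.sample_ids, name="barcode"),
    )


def qc_filter(
    counts: CountMatrix,
    mito_prefix: str = "MT-",
    nmads: float = 3.0,
    max_pct_mito: float | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Remove outlier cells on library size, complexity, and mito fraction.

    Cells outside median +/- nmads * MAD on log(n_umi) or log(n_genes), or
    above median + nmads * MAD on pct_mito, are removed (MAD scaled by
    1.4826). ``max_pct_mito`` overrides the adaptive mito threshold. Raises
    if more than 90% of cells would be removed, which usually means the
    mitochondrial gene tag does not match the data.
    """
    metrics = qc_metrics(counts, mito_prefix)
    if not any(g.startswith(mito_prefix) for g in counts.gene_ids):
        raise SCError(f"no genes tagged with mito prefix {mito_prefix!r}")

    def _bounds(x: np.ndarray) -> tuple[float, float]:
        med = np.median(x)
        mad = _MAD_SCALE * np.median(np.abs(x - med))
        return med - nmads * mad, med + nmads * mad

    log_umi = np.log(np.maximum(metrics["n_umi"].to_numpy(), 1))
    log_genes = np.log(np.maximum(metrics["n_genes"].to_numpy(), 1))
    lo_u, hi_u = _bounds(log_umi)
    lo_g, hi_g = _bounds(log_genes)
    pm = metrics["pct_mito"].to_numpy()
    if max_pct_mito is None:
        med = np.median(pm)
        mito_hi = med + nmads * _MAD_SCALE * np.median(np.abs(pm - med))
    else:
        mito_hi = max_pct_mito
    keep = (
        (log_umi >= lo_u) & (log_umi <= hi_u)
        & (log_genes >= lo_g) & (log_genes <= hi_g)
        & (pm <= mito_hi)
    )
    metrics["kept"] = keep
    if keep.sum() < 0.1 * len(keep):
        raise SCError(
            ">90% of cells failed QC; check the mitochondrial gene tag and thresholds"
        )
    log.info(
        "qc_filter: kept %d / %d cells (log_umi [%.2f, %.2f], mito <= %.2f%%)",
        int(keep.sum()), len(keep), lo_u, hi_u, mito_hi,
    )
    kept_ids = [s for s, k in zip(counts.sample_ids, keep) if k]
    return counts.subset_samples(kept_ids), metrics


def lognorm(counts: CountMatrix, target_sum: float = 1e4) -> NormalizedMatrix:
    """Depth-normalized log2(1 + count / total * target_sum) expression."""
    dense = counts.dense().astype(float)
    totals = dense.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"removed {int(zero.sum())} zero-total cells")
        keep = [s for s, z in zip(counts.sample_ids, zero) if not z]
        counts = counts.subset_samples(keep)
        dense = dense[:, ~zero]
        totals = totals[~zero]
    values = np.log2(1.0 + dense / totals[None, :] * target_sum)
    return NormalizedMatrix(list(counts.gene_ids), list(counts.sample_ids), values, "vst")


def lognorm_scale(
    counts: CountMatrix, target_sum: float = 1e4, clip: float = 10.0
) -> NormalizedMatrix:
    """Log-normalize then z-score each gene across cells, clipped to +/- clip."""
    ln = lognorm(counts, target_sum)
    values = ln.values
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    scaled = np.where(sd > 0, (values - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    scaled = np.clip(scaled, -clip, clip)
    return NormalizedMatrix(list(ln.gene_ids), list(ln.sample_ids), scaled, "log-scaled")


def cell_cycle_score(
    norm: NormalizedMatrix,
    phase_sets: dict[str, set[str]],
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Module scores for S and G2M phase sets, and a phase call per cell.

    Each phase score is the mean expression of the phase genes minus the
    mean over expression-bin-matched control genes (``n_ctrl`` controls per
    phase gene, drawn seeded from ``n_bins`` average-expression bins). A
    cell is assigned the arg-max phase if the best score is positive, else
    G1. ``norm`` should be the log-normalized (unscaled) matrix.
    """
    for phase in ("S", "G2M"):
        if phase not in phase_sets:
            raise SCError(f"phase_sets must contain {phase!r}")
    gene_pos = {g: i for i, g in enumerate(norm.gene_ids)}
    avg = norm.values.mean(axis=1)
    order = np.argsort(avg, kind="stable")
    bin_of = np.empty(len(avg), dtype=int)
    bin_of[order] = np.minimum(np.arange(len(avg)) * n_bins // len(avg), n_bins - 1)
    bins: dict[int, np.ndarray] = {b: np.flatnonzero(bin_of == b) for b in range(n_bins)}

    rng = np.random.default_rng(seed)
    scores = {}
    for phase in ("S", "G2M"):
        idx = np.array([gene_pos[g] for g in sorted(phase_sets[phase]) if g in gene_pos])
        if idx.size == 0:
            raise SCError(f"no {phase} phase genes present in the matrix")
        ctrl: set[int] = set()
        for gi in idx:
            pool = bins[bin_of[gi]]
            take = min(n_ctrl, len(pool))
            ctrl.update(rng.choice(pool, take, replace=False))
        ctrl_idx = np.array(sorted(ctrl))
        scores[phase] = norm.values[idx].mean(axis=0) - norm.values[ctrl_idx].mean(axis=0)

    s, g2m = scores["S"], scores["G2M"]
    phase = np.where(
        np.maximum(s, g2m) <= 0, "G1", np.where(g2m > s, "G2M", "S")
    )
    return pd.DataFrame(
        {"S_score": s, "G2M_score": g2m, "phase": phase},
        index=pd.Index(norm.sample_ids, name="barcode"),
    )


def project_phate1_score(
    scaled: NormalizedMatrix,
    counts: CountMatrix,
    weights: pd.DataFrame | pd.Series,
) -> pd.DataFrame:
    """Per-cell trajectory score: median of weighted scaled expression.

    A gene enters a cell's multiset iff the cell's raw count for it is
    positive and the gene's weight is defined and non-zero; the score is the
    median of {scaled value * weight} over that multiset. Cells with an
    empty multiset get a NaN score and are flagged missing.
    """
    if isinstance(weights, pd.DataFrame):
        wser = weights.loc[weights.get("defined", pd.Series(True, index=weights.index)).astype(bool), "signed_r2"]
    else:
        wser = weights.dropna()
    shared = [g for g in scaled.gene_ids if g in wser.index]
    if not shared:
        raise SCError("no genes shared between weights and matrix")
    sub_scaled = scaled.subset_genes(shared)
    pos = {g: i for i, g in enumerate(counts.gene_ids)}
    sub_counts = counts.subset_samples(scaled.sample_ids).subset_genes(
        np.array([pos[g] for g in shared])
    )
    w = wser.loc[shared].to_numpy(float)
    weighted = sub_scaled.values * w[:, None]
    # a gene enters a cell's multiset only if expressed and non-trivially weighted
    expressed = (sub_counts.dense() > 0) & (w[:, None] != 0)

    n_cells = weighted.shape[1]
    score = np.full(n_cells, np.nan)
    n_used = np.zeros(n_cells, dtype=int)
    for c in range(n_cells):
        vals = weighted[expressed[:, c], c]
        n_used[c] = len(vals)
        if len(vals):
            score[c] = np.median(vals)
    out = pd.DataFrame(
        {"phate1_score": score, "n_genes_used": n_used, "missing": n_used == 0},
        index=pd.Index(scaled.sample_ids, name="barcode"),
    )
    if out["missing"].any():
        log.warning("project_phate1_score: %d cells had empty multisets", int(out["missing"].sum()))
    return out


def rank_cell_clusters(scores: pd.DataFrame, clusters: pd.Series) -> pd.DataFrame:
    """Clusters ordered by median cell score, with per-cluster quartiles."""
    clusters = clusters.reindex(scores.index)
    if clusters.isna().any():
        raise SCError("every scored cell must be clustered")
    rows = []
    for c, idx in scores.groupby(clusters).groups.items():
        vals = scores.loc[idx, "phate1_score"].dropna()
        rows.append(
            (c, len(idx), float(vals.median()), float(vals.quantile(0.25)), float(vals.quantile(0.75)))
        )
    out = pd.DataFrame(rows, columns=["cluster", "n", "median_score", "q25", "q75"]).set_index(
        "cluster"
    )
    out = out.sort_values("median_score", ascending=False)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def cluster_markers_and_enrichment(
    norm: NormalizedMatrix,
    clusters: pd.Series,
    collection,
    universe: set[str] | None = None,
    min_log2fc: float = 0.58,
    max_padj: float = 0.05,
    min_cluster_size: int = 3,
) -> dict:
    """One-vs-rest markers per cluster, both directions, plus ORA of each.

    Positive markers pass (log2fc > min_log2fc, adjusted p < max_padj);
    negative markers mirror the thresholds with log2fc < -min_log2fc. ORA is
    run separately on the positive and the negative marker lists against
    ``collection`` with ``universe`` (default: all genes in the matrix).
    """
    clusters = clusters.reindex(norm.sample_ids)
    if clusters.nunique() < 2:
        raise SCError("need >= 2 clusters")
    universe = universe if universe is not None else set(norm.gene_ids)
    out = {}
    for c in sorted(clusters.unique(), key=str):
        n_c = int((clusters == c).sum())
        if n_c < min_cluster_size:
            warnings.warn(f"cluster {c!r} has {n_c} cells (< {min_cluster_size}); skipped")
            continue
        table = wilcoxon_markers(norm, clusters, c, min_log2fc=min_log2fc, max_padj=max_padj)
        positive = set(table.index[table["passes"]])
        negative = set(
            table.index[(table["avg_log2fc"] < -min_log2fc) & (table["p_adj"] < max_padj)]
        )
        entry = {"markers": table, "positive": positive, "negative": negative}
        for direction, genes in (("positive", positive), ("negative", negative)):
            if genes:
                entry[f"ora_{direction}"] = ora_hypergeometric(
                    genes & universe, universe, collection
                )
            else:
                entry[f"ora_{direction}"] = None
        out[c] = entry
    return out
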