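"""Tumor marker discovery, per-sample marker scores, and group ranking.

Marker genes are found with a two-sided Wilcoxon rank-sum test per gene
(normal approximation with tie correction; exact enumeration when both
groups have <= 8 samples), Bonferroni-adjusted, filtered on average log2
fold change. The per-sample marker score is the median transformed
expression over the passing marker genes; groups (tissues or clusters) are
ranked by median score with pairwise Welch t-tests under Holm correction.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import NormalizedMatrix

log = logging.getLogger("ewstraj")

EXACT_MAX_N = 8


class MarkerError(ValueError):
    pass


def rank_sum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by full enumeration (tie-safe).

    Enumerates every assignment of the pooled values to a group of size
    len(x); the p-value is the fraction of assignments whose rank sum
    deviates from its mean by at least as much as the observed one.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    mean_w = ranks.sum() * n1 / len(pooled)
    d_obs = abs(w_obs - mean_w)
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(comb)].sum()
        total += 1
        if abs(w - mean_w) >= d_obs - 1e-12:
            count += 1
    return count / total


def _rank_sum_normal_p(values: np.ndarray, mask1: np.ndarray) -> np.ndarray:
    """Vectorized two-sided rank-sum p with tie correction, per gene (rows)."""
    n1 = int(mask1.sum())
    n2 = values.shape[1] - n1
    ranks = stats.rankdata(values, axis=1)
    w = ranks[:, mask1].sum(axis=1)
    mean_w = n1 * (values.shape[1] + 1) / 2.0
    # tie correction: sum over tie groups of (t^3 - t)
    tie_term = np.zeros(values.shape[0])
    for i in range(values.shape[0]):
        _, counts = np.unique(values[i], return_counts=True)
        tie_term[i] = np.sum(counts**3 - counts)
    ntot = values.shape[1]
    var_w = n1 * n2 / 12.0 * ((ntot + 1) - tie_term / (ntot * (ntot - 1)))
    p = np.ones(values.shape[0])
    pos = var_w > 0
    z = np.zeros_like(p)
    # continuity correction: the rank-sum statistic moves in half-rank steps
    z[pos] = np.maximum(np.abs(w[pos] - mean_w) - 0.5, 0.0) / np.sqrt(var_w[pos])
    # Iman's normal/t blend: markedly more accurate than the plain normal
    # approximation at small-to-moderate group sizes
    df = ntot - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(
            z**2 < ntot - 1, z * np.sqrt(df / np.maximum(ntot - 1 - z**2, 1e-12)), np.inf
        )
    p[pos] = (stats.norm.sf(z[pos]) + stats.t.sf(t[pos], df))
    return np.minimum(p, 1.0)


def wilcoxon_markers(
    norm: NormalizedMatrix,
    labels: pd.Series,
    target_group: str,
    min_log2fc: float = 0.58,
    max_padj: float = 1e-50,
) -> pd.DataFrame:
    """Per-gene rank-sum marker table for ``target_group`` vs the rest.

    Fold changes are computed on the pseudo-normalized scale: the transformed
    values are inverted with 2^x - 1, group means taken, and
    log2((mean_target + 1) / (mean_rest + 1)) reported. Bonferroni
    adjustment across genes; ``passes`` requires both thresholds.
    """
    lab = labels.reindex(norm.sample_ids)
    mask1 = (lab == target_group).to_numpy()
    mask2 = ~mask1
    if mask1.sum() == 0 or mask2.sum() == 0:
        raise MarkerError("both groups must be non-empty")
    values = norm.values
    n_genes = values.shape[0]

    if mask1.sum() <= EXACT_MAX_N and mask2.sum() <= EXACT_MAX_N:
        p = np.array(
            [rank_sum_exact_p(values[g, mask1], values[g, mask2]) for g in range(n_genes)]
        )
    else:
        p = _rank_sum_normal_p(values, mask1)

    expm = np.power(2.0, values) - 1.0
    mean_t = expm[:, mask1].mean(axis=1)
    mean_r = expm[:, mask2].mean(axis=1)
    log2fc = np.log2((mean_t + 1.0) / (mean_r + 1.0))
    constant = values.ptp(axis=1) == 0 if hasattr(values, "ptp") else np.ptp(values, axis=1) == 0
    p[constant] = 1.0
    log2fc[constant] = 0.0

    p_adj = np.minimum(p * n_genes, 1.0)
    passes = (log2fc > min_log2fc) & (p_adj < max_padj)
    return pd.DataFrame(
        {"avg_log2fc": log2fc, "p": p, "p_adj": p_adj, "passes": passes},
        index=pd.Index(norm.gene_ids, name="gene_id"),
    )


def marker_score(norm: NormalizedMatrix, marker_genes: list[str] | set[str]) -> pd.Series:
    """Per-sample median transformed expression over the marker genes."""
    present = [g for g in norm.gene_ids if g in set(marker_genes)]
    if not present:
        raise MarkerError("no marker genes present in the matrix")
    sub = norm.subset_genes(present)
    return pd.Series(np.median(sub.values, axis=0), index=norm.sample_ids, name="marker_score")


@dataclass
class GroupRanking:
    table: pd.DataFrame        # per group: n, median_score, rank, tested flag
    pairwise: pd.DataFrame     # group_a, group_b, t, p, p_holm
    top_groups: list[str]      # groups not significantly below the leader


def rank_groups(scores: pd.Series, grouping: pd.Series, alpha: float = 0.05) -> GroupRanking:
    """Rank sample groups by median marker score with pairwise Welch t-tests.

    Groups of size 1 are kept in the ranking but flagged and excluded from
    testing. The top-group set contains the leader plus every tested group
    whose Holm-adjusted test against the leader is not significant.
    """
    grouping = grouping.reindex(scores.index)
    if grouping.nunique() < 2:
        raise MarkerError("need >= 2 groups")
    stats_rows = []
    for g, idx in scores.groupby(grouping).groups.items():
        vals = scores[idx]
        stats_rows.append((g, len(vals), float(np.median(vals))))
    table = pd.DataFrame(stats_rows, columns=["group", "n", "median_score"]).set_index("group")
    table = table.sort_values("median_score", ascending=False)
    table["rank"] = np.arange(1, len(table) + 1)
    table["tested"] = table["n"] >= 2

    tested = [g for g in table.index if table.loc[g, "tested"]]
    pairs, tvals, pvals = [], [], []
    for a, b in itertools.combinations(tested, 2):
        va = scores[grouping == a].to_numpy()
        vb = scores[grouping == b].to_numpy()
        if np.ptp(np.concatenate([va, vb])) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(va, vb, equal_var=False)
        pairs.append((a, b))
        tvals.append(float(t))
        pvals.append(float(p))
    if pairs:
        p_holm = _holm(np.array(pvals))
    else:
        p_holm = np.array([])
    pairwise = pd.DataFrame(
        {
            "group_a": [a for a, _ in pairs],
            "group_b": [b for _, b in pairs],
            "t": tvals,
            "p": pvals,
            "p_holm": p_holm,
        }
    )

    leader = table.index[0]
    top = [leader]
    for g in tested:
        if g == leader:
            continue
        row = pairwise[
            ((pairwise.group_a == leader) & (pairwise.group_b == g))
            | ((pairwise.group_a == g) & (pairwise.group_b == leader))
        ]
        if row.empty or float(row["p_holm"].iloc[0]) >= alpha:
            top.append(g)
    return GroupRanking(table, pairwise, top)


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (monotone, bounded by 1)."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(running, 1.0)
    return adj


def select_top_clusters(cluster_medians: pd.Series, top_k: int | None = None) -> list:
    """Split clusters into high/low marker-score groups; return the high group.

    With ``top_k`` given, simply the top-k clusters by median score.
    Otherwise the sorted cluster medians are cut at the contiguous split that
    minimizes total within-group variance (1-D two-means), and the
    high-scoring group is returned. Deterministic; requires >= 2 clusters.
    """
    med = cluster_medians.sort_values(ascending=False)
    if top_k is not None:
        return list(med.index[:top_k])
    if len(med) < 2:
        return list(med.index)
    vals = med.to_numpy(float)
    best_cut, best_sse = 1, np.inf
    for cut in range(1, len(vals)):
        sse = vals[:cut].var() * cut + vals[cut:].var() * (len(vals) - cut)
        if sse < best_sse:
            best_sse, best_cut = sse, cut
    return list(med.index[:best_cut])


def composition_enrichment(tissues: pd.Series, clusters: pd.Series) -> pd.DataFrame:
    """Tissue x cluster composition, column-scaled but not centered.

    Entry (t, c) before scaling is the fraction of tissue t's samples falling
    in cluster c (rows sum to 1); each column is then divided by its
    population standard deviation. Zero-variance columns are left unscaled
    with a warning.
    """
    clusters = clusters.reindex(tissues.index)
    if clusters.isna().any():
        raise MarkerError("clusters must cover all samples")
    counts = pd.crosstab(tissues, clusters)
    props = counts.div(counts.sum(axis=1), axis=0)
    scaled = props.copy().astype(float)
    for c in scaled.columns:
        sd = scaled[c].std(ddof=0)
        if sd == 0:
            warnings.warn(f"cluster {c!r} has zero-variance composition; left unscaled")
            continue
        scaled[c] = scaled[c] / sd
    return scaled
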