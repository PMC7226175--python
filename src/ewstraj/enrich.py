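"""Preranked GSEA, hypergeometric over-representation, and gene-set curation.

GSEA uses the weighted Kolmogorov-Smirnov running sum on a ranked gene list:
hits increment proportionally to |score|^p, misses decrement uniformly by
1/(N - N_hit); the enrichment score is the running-sum extremum, and
significance comes from gene-label permutation with sign-stratified
normalization (NES = ES / mean |permuted ES| of the same sign). ORA is the
upper-tail hypergeometric test of a query list's overlap with each set in a
stated universe. Both adjust p-values across sets by Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSetCollection

log = logging.getLogger("ewstraj")


class EnrichError(ValueError):
    pass


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, bounded by 1)."""
    p = np.asarray(p, float)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        adj[i] = running
    return adj


def _es_batch(w: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Enrichment scores for batches of hit-index sets.

    ``w`` is |score|^p over the ranked list (length N); ``idx`` is a B x m
    array of hit positions, each row sorted ascending. The running sum is
    piecewise linear between hits, so its extremum is attained immediately
    before or after a hit; both candidate sets are evaluated in closed form.
    """
    idx = np.atleast_2d(idx)
    B, m = idx.shape
    N = len(w)
    W = w[idx]
    H = np.cumsum(W, axis=1)
    Htot = H[:, -1].copy()
    ok = Htot > 0
    Htot[~ok] = 1.0
    miss = 1.0 / (N - m)
    j = np.arange(m)
    # idx[j] - j misses precede the j-th hit; the extremum of the piecewise
    # linear running sum is attained just before or just after a hit
    after = H / Htot[:, None] - (idx - j) * miss
    before = (H - W) / Htot[:, None] - (idx - j) * miss
    cand = np.concatenate([after, before], axis=1)
    pick = np.argmax(np.abs(cand), axis=1)
    es = cand[np.arange(B), pick]
    es[~ok] = 0.0
    return es


def _leading_edge(w: np.ndarray, idx: np.ndarray, genes: np.ndarray, es: float) -> list[str]:
    """Hit genes between the start (or end) of the list and the ES extremum."""
    W = w[idx]
    H = np.cumsum(W)
    Htot = H[-1] if H[-1] > 0 else 1.0
    m = len(idx)
    N = len(w)
    miss = 1.0 / (N - m)
    j = np.arange(m)
    after = H / Htot - (idx - j) * miss
    before = (H - W) / Htot - (idx - j) * miss
    if es >= 0:
        jstar = int(np.argmax(after))
        return [str(g) for g in genes[idx[: jstar + 1]]]
    jstar = int(np.argmin(before))
    return [str(g) for g in genes[idx[jstar:]]]


def preranked_gsea(
    ranking: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 2000,
    weight_p: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA of every set in ``collection`` against ``ranking``.

    ``ranking`` maps gene -> real score (e.g. signed R^2); duplicate gene ids
    are an error, NaN scores are dropped. Significance is by gene-label
    permutation: random same-size index sets share one draw per set size, and
    p = (1 + #{same-sign permuted ES at least as extreme}) / (1 + #{same-sign
    permuted ES}). Sets smaller than ``min_size`` (within the ranking),
    larger than ``max_size``, or spanning the whole list are skipped.
    """
    if ranking.index.has_duplicates:
        raise EnrichError("ranking has duplicate gene ids")
    ranking = ranking.dropna()
    order = sorted(ranking.index, key=lambda g: (-ranking[g], g))
    genes = np.array(order)
    scores = ranking.loc[order].to_numpy(float)
    N = len(genes)
    w = np.abs(scores) ** weight_p
    pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    rows = []
    perm_cache: dict[int, np.ndarray] = {}
    for name in collection.names():
        hit = np.array(sorted(pos[g] for g in collection[name] if g in pos), dtype=int)
        m = len(hit)
        if m < min_size or m > max_size:
            log.info("GSEA: set %r size %d outside [%d, %d]; skipped", name, m, min_size, max_size)
            continue
        if m >= N:
            log.info("GSEA: set %r covers the whole ranking; skipped", name)
            continue
        es = float(_es_batch(w, hit[None, :])[0])
        if m not in perm_cache:
            draws = np.empty((n_perm, m), dtype=int)
            for b in range(n_perm):
                draws[b] = rng.choice(N, m, replace=False)
            draws.sort(axis=1)
            perm_cache[m] = draws
        es_null = _es_batch(w, perm_cache[m])
        same = es_null >= 0 if es >= 0 else es_null < 0
        n_same = int(same.sum())
        n_extreme = int((np.abs(es_null[same]) >= abs(es) - 1e-15).sum())
        p = (1 + n_extreme) / (1 + n_same)
        mean_same = np.abs(es_null[same]).mean() if n_same else np.nan
        nes = es / mean_same if n_same and mean_same > 0 else np.nan
        le = _leading_edge(w, hit, genes, es)
        rows.append((name, m, es, nes, p, ",".join(le)))

    out = pd.DataFrame(
        rows, columns=["name", "size", "es", "nes", "p", "leading_edge"]
    ).set_index("name")
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.array([])
    out["method"] = "gsea"
    return out


def ora_hypergeometric(
    query: set[str],
    universe: set[str],
    collection: GeneSetCollection,
    min_overlap_size: int = 1,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` in each set.

    For a set S: k = |query & S & universe| successes observed among
    n = |query| draws from a universe of size N containing K = |S & universe|
    successes; p = P(X >= k). BH adjustment across sets.
    """
    query = set(query)
    universe = set(universe)
    if not query:
        raise EnrichError("empty query")
    if not query <= universe:
        raise EnrichError("query must be a subset of the universe")
    N = len(universe)
    n = len(query)
    rows = []
    for name in collection.names():
        S = collection[name] & universe
        K = len(S)
        overlap = query & S
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((name, K, k, p, ",".join(sorted(overlap))))
    out = pd.DataFrame(rows, columns=["name", "size", "overlap", "p", "overlap_genes"]).set_index(
        "name"
    )
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.array([])
    out["method"] = "ora"
    return out


def compare_enrichments(res_a: pd.DataFrame, res_b: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Overlap of two enrichment results computed on the same collection.

    Reports the significant sets of each result (BH p_adj < alpha), the
    shared set names, and the upper-tail hypergeometric p of the overlap
    with the collection as the universe.
    """
    if set(res_a.index) != set(res_b.index):
        raise EnrichError("results were computed on different collections")
    n_universe = len(res_a)
    sig_a = set(res_a.index[res_a["p_adj"] < alpha])
    sig_b = set(res_b.index[res_b["p_adj"] < alpha])
    shared = sig_a & sig_b
    p = float(stats.hypergeom.sf(len(shared) - 1, n_universe, len(sig_a), len(sig_b)))
    return {
        "significant_a": sorted(sig_a),
        "significant_b": sorted(sig_b),
        "shared": sorted(shared),
        "n_shared": len(shared),
        "p_overlap": p,
        "alpha": alpha,
        "n_universe": n_universe,
    }


def assign_meta_categories(
    set_names: list[str], regex_dictionary: dict[str, str], return_assignments: bool = False
):
    """Assign set names to categories by case-insensitive regex matching.

    A name matching several patterns is counted in every matching category;
    names matching none are counted as "uncategorized".
    """
    compiled = {cat: re.compile(pat, re.IGNORECASE) for cat, pat in regex_dictionary.items()}
    counts = {cat: 0 for cat in compiled}
    counts["uncategorized"] = 0
    assignments: dict[str, list[str]] = {}
    for name in set_names:
        cats = [cat for cat, rx in compiled.items() if rx.search(name)]
        if not cats:
            cats = ["uncategorized"]
        for cat in cats:
            counts[cat] += 1
        assignments[name] = cats
    if return_assignments:
        return counts, assignments
    return counts


def curate_collection(
    source: GeneSetCollection,
    include_regex: str | None = None,
    censor_names: list[str] | None = None,
    derived_ops: list[dict] | None = None,
) -> GeneSetCollection:
    """Curate a collection: regex gather, censor, and derive composite sets.

    ``derived_ops`` entries look like ``{"name": NEW, "op": "intersection" |
    "union", "sets": [A, B, ...]}`` and may reference sets of the *source*
    collection (so intersections can involve non-gathered sets). Every
    action is appended to the curation log.
    """
    provenance = list(source.provenance)
    if include_regex is not None:
        rx = re.compile(include_regex, re.IGNORECASE)
        sets = {k: set(v) for k, v in source.sets.items() if rx.search(k)}
        provenance.append(f"include_regex:{include_regex} -> {len(sets)} sets")
    else:
        sets = {k: set(v) for k, v in source.sets.items()}
    for name in censor_names or []:
        if name in sets:
            del sets[name]
            provenance.append(f"censored:{name}")
        else:
            provenance.append(f"censor-miss:{name}")
    for op in derived_ops or []:
        refs = []
        for ref in op["sets"]:
            if ref in sets:
                refs.append(sets[ref])
            elif ref in source.sets:
                refs.append(set(source.sets[ref]))
            else:
                raise EnrichError(f"derived op references missing set {ref!r}")
        if op["op"] == "intersection":
            new = set.intersection(*refs)
        elif op["op"] == "union":
            new = set.union(*refs)
        else:
            raise EnrichError(f"unknown derived op {op['op']!r}")
        sets[op["name"]] = new
        provenance.append(f"derived:{op['name']}={op['op']}({','.join(op['sets'])})")
    return GeneSetCollection(sets, provenance)
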