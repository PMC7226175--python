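"""Dimensionality reduction, graph clustering, and trajectory embedding.

The trajectory embedding is a diffusion-potential method: an adaptive
alpha-decay kernel (bandwidth = distance to the k-th neighbor) is
symmetrized and row-normalized into a Markov matrix, diffused t steps, the
potential -log(P^t + eps) is taken, and classical MDS of the potential
distances gives the coordinates. Axis 1 of the embedding ("PHATE_1") is the
trajectory coordinate; its sign is fixed by anchoring a designated group
(mesodermal in the intended analysis) to the positive side.
"""

from __future__ import annotations

import logging
import random as _random
import warnings

import igraph as ig
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA as _SKPCA

from .containers import Embedding, NormalizedMatrix

log = logging.getLogger("ewstraj")


class ManifoldError(ValueError):
    pass


def _fix_signs(components: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic sign convention: largest-magnitude loading positive."""
    for j in range(components.shape[0]):
        i = int(np.argmax(np.abs(components[j])))
        if components[j, i] < 0:
            components[j] *= -1.0
            scores[:, j] *= -1.0
    return components, scores


def pca(norm: NormalizedMatrix, n_components: int) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples in gene space (genes centered), full SVD solver.

    Returns (scores: samples x PCs, explained variance ratio). Components
    beyond the matrix rank are truncated with a warning.
    """
    X = norm.values.T  # samples x genes
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank bound {max_rank}; truncating"
        )
        n_components = max_rank
    model = _SKPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    _fix_signs(model.components_, scores)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=norm.sample_ids, columns=cols),
        model.explained_variance_ratio_,
    )


def _knn_lists(X: np.ndarray, k: int) -> list[list[int]]:
    """k nearest neighbors per point (self excluded), ties broken by index."""
    n = X.shape[0]
    if not (0 < k < n):
        raise ManifoldError("k must satisfy 0 < k < n_samples")
    D = squareform(pdist(X))
    out = []
    for i in range(n):
        order = sorted(range(n), key=lambda j: (D[i, j], j))
        out.append([j for j in order if j != i][:k])
    return out


def knn_graph(scores: pd.DataFrame | np.ndarray, k: int) -> ig.Graph:
    """Euclidean kNN graph with shared-nearest-neighbor (Jaccard) edge weights.

    Directed kNN edges are symmetrized by union; the weight of edge (i, j)
    is |N(i) & N(j)| / |N(i) | N(j)| where N includes the point itself and
    its k nearest neighbors.
    """
    if isinstance(scores, pd.DataFrame):
        names = [str(s) for s in scores.index]
        X = scores.to_numpy(float)
    else:
        X = np.asarray(scores, float)
        names = [str(i) for i in range(X.shape[0])]
    neigh = _knn_lists(X, k)
    sets = [frozenset([i, *nb]) for i, nb in enumerate(neigh)]
    edges, weights = [], []
    seen = set()
    for i, nb in enumerate(neigh):
        for j in nb:
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            inter = len(sets[i] & sets[j])
            union = len(sets[i] | sets[j])
            edges.append(key)
            weights.append(inter / union)
    g = ig.Graph(n=X.shape[0], edges=edges)
    g.vs["name"] = names
    g.es["weight"] = weights
    return g


def louvain(graph: ig.Graph, resolution: float = 1.0, seed: int = 0) -> pd.Series:
    """Louvain (multilevel modularity) clustering with a seeded node order."""
    if graph.vcount() == 0:
        raise ManifoldError("empty graph")
    state = _random.getstate()
    try:
        _random.seed(seed)
        part = graph.community_multilevel(weights="weight", resolution=resolution)
    finally:
        _random.setstate(state)
    labels = pd.Series(part.membership, index=graph.vs["name"], name="cluster")
    return labels


def embed_trajectory(
    data: pd.DataFrame | NormalizedMatrix,
    k: int = 15,
    decay: float = 10.0,
    t: int = 40,
    n_dims: int = 3,
    kernel_eps: float = 1e-7,
) -> Embedding:
    """Diffusion-potential embedding of samples.

    ``data`` is samples x features (e.g. PCA scores) or a NormalizedMatrix
    (transposed internally). Deterministic: the only numerics are dense
    linear algebra with a fixed sign convention.
    """
    if isinstance(data, NormalizedMatrix):
        X = data.values.T
        names = list(data.sample_ids)
    else:
        X = data.to_numpy(float)
        names = [str(s) for s in data.index]
    n = X.shape[0]
    if n_dims not in (2, 3):
        raise ManifoldError("n_dims must be 2 or 3")
    if not (0 < k < n):
        raise ManifoldError("embed k must satisfy 0 < k < n_samples")

    D = squareform(pdist(X))
    # adaptive bandwidth: distance to the k-th nearest neighbor (self excluded)
    eps_k = np.sort(D, axis=1)[:, k]
    eps_k = np.maximum(eps_k, 1e-12)
    with np.errstate(over="ignore"):
        Ki = np.exp(-((D / eps_k[:, None]) ** decay))
        Kj = np.exp(-((D / eps_k[None, :]) ** decay))
    K = 0.5 * (Ki + Kj)

    # connectivity check on the thresholded kernel
    adj = K > 1e-12
    comp_labels = _connected_components(adj)
    if comp_labels.max() > 0:
        raise ManifoldError(
            "kernel graph is disconnected; increase k or decrease decay"
        )

    P = K / K.sum(axis=1, keepdims=True)
    Pt = np.linalg.matrix_power(P, t)
    U = -np.log(Pt + kernel_eps)
    coords = _classical_mds(squareform(pdist(U)), n_dims)
    return Embedding(names, coords, params={"k": k, "decay": decay, "t": t, "n_dims": n_dims})


def _connected_components(adj: np.ndarray) -> np.ndarray:
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    _, labels = connected_components(csr_matrix(adj), directed=False)
    return labels


def _classical_mds(D: np.ndarray, n_dims: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D**2) @ J
    B = 0.5 * (B + B.T)
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:n_dims]
    vals = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(vals)[None, :]
    # deterministic sign: largest-magnitude coordinate positive per axis
    for j in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] *= -1.0
    return coords


def orient_axis(emb: Embedding, labels: pd.Series, anchor_group: str) -> Embedding:
    """Fix the sign of axis 1 so the anchor group's mean coordinate is >= 0."""
    anchor = [s for s in emb.sample_ids if labels.get(s) == anchor_group]
    if not anchor:
        raise ManifoldError(f"anchor group {anchor_group!r} has no samples in embedding")
    idx = [emb.sample_ids.index(s) for s in anchor]
    coords = emb.coords.copy()
    if coords[idx, 0].mean() < 0:
        coords[:, 0] *= -1.0
    return Embedding(list(emb.sample_ids), coords, params=dict(emb.params), axis1_anchor=anchor_group)


def prune_non_trajectory(
    emb: Embedding,
    is_tumor: pd.Series,
    k: int = 15,
    resolution: float = 1.0,
    radius: int = 3,
    seed: int = 0,
) -> list[str]:
    """Samples whose embedding cluster lies near tumor samples.

    Louvain clusters are computed on the kNN graph of the embedding
    coordinates; a cluster is retained iff any of its members is within
    ``radius`` graph hops of a tumor sample. Returns the retained sample ids
    (original order).
    """
    tumor_ids = [s for s in emb.sample_ids if bool(is_tumor.get(s, False))]
    if not tumor_ids:
        raise ManifoldError("no tumor samples present; pruning undefined")
    g = knn_graph(pd.DataFrame(emb.coords, index=emb.sample_ids), k=min(k, len(emb.sample_ids) - 1))
    clusters = louvain(g, resolution=resolution, seed=seed)
    tumor_vids = [g.vs.find(name=s).index for s in tumor_ids]
    hops = np.asarray(g.distances(source=tumor_vids))  # tumors x samples, hop counts
    min_hops = hops.min(axis=0)
    near = pd.Series(min_hops <= radius, index=g.vs["name"])
    keep_clusters = {c for c, members in clusters.groupby(clusters) if near[members.index].any()}
    retained = [s for s in emb.sample_ids if clusters[s] in keep_clusters]
    if not retained:
        raise ManifoldError("pruning removed every sample")
    log.info("prune_non_trajectory retained %d / %d samples", len(retained), len(emb.sample_ids))
    return retained
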