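"""Gene filtering, size-factor normalization, VST, and variable-gene selection.

Size factors use the median-of-ratios estimator: each sample's factor is the
median, over genes expressed in every sample, of the ratio of its count to
the gene's geometric mean across samples — then rescaled so the factors have
geometric mean 1. The variance-stabilizing transform applied downstream is
log2(count / factor + 1); downstream statistics (medians, correlations, rank
tests) depend only on a monotone variance-stabilizing map, so a fitted
mean-dispersion transform is deliberately not used.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import CountMatrix, NormalizedMatrix

log = logging.getLogger("ewstraj")


class NormalizationError(ValueError):
    pass


def filter_genes(counts: CountMatrix, max_zero_fraction: float = 0.10) -> CountMatrix:
    """Discard genes with zero counts in ``max_zero_fraction`` or more of samples.

    The threshold is inclusive: a gene whose zero fraction equals the
    threshold is discarded. Gene order is preserved; idempotent.
    """
    if not (0 < max_zero_fraction <= 1):
        raise NormalizationError("max_zero_fraction must lie in (0, 1]")
    dense = counts.dense()
    zero_frac = (dense == 0).mean(axis=1)
    keep = zero_frac < max_zero_fraction
    if not keep.any():
        raise NormalizationError("gene filter removed every gene")
    return counts.subset_genes(keep)


def size_factors_median_ratio(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1."""
    dense = counts.dense().astype(float)
    if dense.shape[1] < 2:
        raise NormalizationError("size factors require >= 2 samples")
    all_positive = (dense > 0).all(axis=1)
    if not all_positive.any():
        raise NormalizationError(
            "no gene has positive counts in every sample; run filter_genes first"
        )
    ref = dense[all_positive]
    log_geo_mean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geo_mean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def vst(counts: CountMatrix, factors: pd.Series) -> NormalizedMatrix:
    """log2(normalized count + 1) on median-of-ratios normalized counts."""
    f = factors.reindex(counts.sample_ids).to_numpy(float)
    if np.any(~np.isfinite(f)) or np.any(f <= 0):
        raise NormalizationError("invalid size factors for this matrix")
    values = np.log2(counts.dense() / f[None, :] + 1.0)
    return NormalizedMatrix(list(counts.gene_ids), list(counts.sample_ids), values, "vst")


def median_by_ratio_normalize(counts: CountMatrix, log_scale: bool = True) -> NormalizedMatrix:
    """Median-of-ratios normalized counts for the trajectory-correlation stage.

    With ``log_scale`` (default) values are log2(normalized + 1); the tag
    records which scale was produced.
    """
    factors = size_factors_median_ratio(counts)
    normed = counts.dense() / factors.to_numpy(float)[None, :]
    values = np.log2(normed + 1.0) if log_scale else normed
    return NormalizedMatrix(
        list(counts.gene_ids), list(counts.sample_ids), values, "median-by-ratio"
    )


def select_variable_genes(norm: NormalizedMatrix, n: int) -> list[str]:
    """The ``n`` genes with largest variance; ties broken by gene id."""
    if n <= 0:
        raise NormalizationError("n must be positive")
    if n > len(norm.gene_ids):
        raise NormalizationError("n exceeds gene count")
    variances = norm.values.var(axis=1, ddof=0)
    order = sorted(range(len(norm.gene_ids)), key=lambda i: (-variances[i], norm.gene_ids[i]))
    return [norm.gene_ids[i] for i in order[:n]]
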