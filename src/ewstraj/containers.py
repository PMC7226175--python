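"""Core in-memory containers shared by every pipeline stage.

Counts are always oriented genes x samples (or genes x cells), matching the
convention of bulk RNA-seq compendia. Identifier lists are order-significant
and must be unique; every container validates on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp


class FormatError(ValueError):
    """Malformed input file (dimension mismatch, bad field count, ...)."""


class ValidationError(ValueError):
    """Structurally valid file whose content violates a container invariant."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for x in ids:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise ValidationError(f"duplicate {what} identifiers: {sorted(set(dups))[:5]}")
    return ids


@dataclass
class CountMatrix:
    """Non-negative integer expression counts, genes x samples.

    ``counts`` may be a dense ndarray or a scipy sparse matrix; all pipeline
    math goes through :meth:`dense`.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray | sp.spmatrix

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        data = self.counts.data if sp.issparse(self.counts) else np.asarray(self.counts)
        if data.size:
            if np.any(data < 0):
                raise ValidationError("negative counts")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("non-integer counts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def dense(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense(), dtype=np.int64)
        return np.asarray(self.counts, dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense(), index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        """Subset by boolean mask or integer index array, order preserved."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        genes = [self.gene_ids[i] for i in keep]
        mat = self.counts[keep, :] if not sp.issparse(self.counts) else self.counts.tocsr()[keep, :]
        return CountMatrix(genes, list(self.sample_ids), mat)

    def subset_samples(self, keep_ids: Sequence[str]) -> "CountMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in keep_ids], dtype=int)
        mat = self.counts[:, idx] if not sp.issparse(self.counts) else self.counts.tocsc()[:, idx]
        return CountMatrix(list(self.gene_ids), [str(s) for s in keep_ids], mat)


@dataclass
class NormalizedMatrix:
    """Real-valued transformed expression, genes x samples."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    transform_tag: str  # {"vst", "median-by-ratio", "log-scaled"}

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError("values shape does not match identifier lists")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite values in normalized matrix")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, keep_ids: Sequence[str]) -> "NormalizedMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in keep_ids], dtype=int)
        return NormalizedMatrix(
            list(self.gene_ids), [str(s) for s in keep_ids], self.values[:, idx], self.transform_tag
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "NormalizedMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = np.array([pos[g] for g in gene_ids], dtype=int)
        return NormalizedMatrix(
            [str(g) for g in gene_ids], list(self.sample_ids), self.values[idx, :], self.transform_tag
        )


SAMPLE_META_COLUMNS = ["tissue", "is_tumor", "study", "intervention", "condition_pair"]


def validate_sample_meta(meta: pd.DataFrame, counts: CountMatrix | None = None) -> pd.DataFrame:
    """Check a sample-metadata table against its companion count matrix.

    The index is the sample identifier; ``tissue``, ``is_tumor`` and ``study``
    are required, ``intervention`` / ``condition_pair`` optional.
    """
    if meta.index.has_duplicates:
        raise ValidationError("duplicate sample_id in metadata")
    for col in ("tissue", "is_tumor", "study"):
        if col not in meta.columns:
            raise ValidationError(f"metadata missing required column '{col}'")
    if counts is not None:
        missing = set(counts.sample_ids) - set(meta.index.astype(str))
        if missing:
            raise ValidationError(f"samples absent from metadata: {sorted(missing)[:5]}")
    return meta


@dataclass
class Embedding:
    """Low-dimensional sample coordinates with an orientable first axis."""

    sample_ids: list[str]
    coords: np.ndarray  # samples x n_dims
    params: dict = field(default_factory=dict)
    axis1_anchor: str | None = None

    def __post_init__(self) -> None:
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[0] != len(self.sample_ids):
            raise FormatError("coords must be samples x n_dims")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite embedding coordinates")

    @property
    def axis1(self) -> pd.Series:
        return pd.Series(self.coords[:, 0], index=self.sample_ids, name="axis1")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"dim{i + 1}" for i in range(self.coords.shape[1])]
        return pd.DataFrame(self.coords, index=self.sample_ids, columns=cols)


@dataclass
class GeneSetCollection:
    """Named gene sets plus a provenance/curation log."""

    sets: dict[str, set[str]]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique(list(self.sets), "gene set")
        self.sets = {str(k): {str(g) for g in v} for k, v in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)
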