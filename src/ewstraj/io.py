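"""Readers and writers for the pipeline's on-disk formats.

Raw counts travel as Matrix Market triplets (matrix.mtx + genes.tsv +
barcodes.tsv, genes x samples) or dense TSV; every intermediate stage output
is TSV so runs are human-inspectable; gene sets are GMT; ground truth and run
manifests are JSON.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import (
    CountMatrix,
    FormatError,
    GeneSetCollection,
    NormalizedMatrix,
    ValidationError,
    validate_sample_meta,
)

log = logging.getLogger("ewstraj")

MTX_MATRIX = "matrix.mtx"
MTX_GENES = "genes.tsv"
MTX_BARCODES = "barcodes.tsv"


def _read_id_file(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_counts(path: str | os.PathLike, format: str = "tsv-dense") -> CountMatrix:
    """Read a gene x sample count matrix.

    ``format="mtx-triplet"`` expects a directory holding ``matrix.mtx``,
    ``genes.tsv`` and ``barcodes.tsv``; ``format="tsv-dense"`` expects a TSV
    with gene identifiers in the first column and sample identifiers as the
    header row.
    """
    path = Path(path)
    if format == "mtx-triplet":
        mtx = path / MTX_MATRIX
        if not mtx.exists():
            raise FormatError(f"missing {mtx}")
        mat = scipy.io.mmread(mtx)
        genes = _read_id_file(path / MTX_GENES)
        samples = _read_id_file(path / MTX_BARCODES)
        if mat.shape != (len(genes), len(samples)):
            raise FormatError(
                f"matrix is {mat.shape} but side files list "
                f"{len(genes)} genes and {len(samples)} barcodes"
            )
        data = mat.data if sp.issparse(mat) else np.asarray(mat)
        if data.size and not np.allclose(data, np.round(data)):
            raise ValidationError("non-integer counts in Matrix Market file")
        return CountMatrix(genes, samples, sp.csr_matrix(mat, dtype=np.int64))
    if format == "tsv-dense":
        df = pd.read_csv(path, sep="\t", index_col=0)
        values = df.to_numpy()
        if values.size and not np.allclose(values.astype(float), np.round(values.astype(float))):
            raise ValidationError("non-integer counts in TSV")
        return CountMatrix(
            [str(g) for g in df.index],
            [str(s) for s in df.columns],
            values.astype(np.int64),
        )
    raise ValueError(f"unknown count format {format!r}")


def write_counts(counts: CountMatrix, path: str | os.PathLike, format: str = "tsv-dense") -> None:
    path = Path(path)
    if format == "mtx-triplet":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / MTX_MATRIX, sp.coo_matrix(counts.counts))
        (path / MTX_GENES).write_text("".join(f"{g}\n" for g in counts.gene_ids))
        (path / MTX_BARCODES).write_text("".join(f"{s}\n" for s in counts.sample_ids))
        return
    if format == "tsv-dense":
        counts.to_frame().to_csv(path, sep="\t", index_label="gene_id")
        return
    raise ValueError(f"unknown count format {format!r}")


def read_sample_meta(path: str | os.PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"metadata file not found: {path}")
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    meta.index = meta.index.astype(str)
    if "is_tumor" in meta.columns:
        meta["is_tumor"] = meta["is_tumor"].astype(bool)
    return validate_sample_meta(meta)


def write_sample_meta(meta: pd.DataFrame, path: str | os.PathLike) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_normalized(path: str | os.PathLike, transform_tag: str) -> NormalizedMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return NormalizedMatrix(
        [str(g) for g in df.index], [str(s) for s in df.columns], df.to_numpy(float), transform_tag
    )


def write_normalized(norm: NormalizedMatrix, path: str | os.PathLike) -> None:
    norm.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Parse a GMT gene-set file (name, description, member genes).

    Duplicate genes within a set are dropped; empty sets are dropped with a
    warning. Lines with fewer than three fields are a format error.
    """
    sets: dict[str, set[str]] = {}
    provenance = [f"read_gmt:{path}"]
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields (< 3)")
            name = fields[0]
            genes = {g for g in fields[2:] if g}
            if not genes:
                log.warning("GMT set %r is empty after deduplication; dropped", name)
                continue
            if name in sets:
                raise ValidationError(f"duplicate gene set name {name!r}")
            sets[name] = genes
    return GeneSetCollection(sets, provenance)


def write_gmt(collection: GeneSetCollection, path: str | os.PathLike, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def write_embedding(emb, path: str | os.PathLike) -> None:
    emb.to_frame().to_csv(path, sep="\t", index_label="sample_id")
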