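"""Pipeline configuration.

Defaults mirror the published compendium analysis: genes with zero counts in
10% or more of samples discarded, top 10,000 variable genes, top 100
principal components, marker thresholds log2FC > 0.58 and adjusted
p < 1e-50. Note that the marker p-value default is calibrated to a ~40,000
sample compendium; runs on small simulated cohorts should pass a
sample-size-appropriate ``max_padj`` (e.g. 0.05).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass

import numpy as np
import yaml


@dataclass
class PipelineConfig:
    seed: int = 0
    # gene filtering
    max_zero_fraction: float = 0.10
    # variable genes / PCA / graph
    n_variable_genes: int = 10_000
    n_pcs: int = 100
    knn_k: int = 20
    louvain_resolution: float = 1.0
    # trajectory embedding (diffusion potential)
    embed_k: int = 15
    embed_decay: float = 10.0
    embed_t: int = 40
    embed_n_dims: int = 3
    prune_radius: int = 3
    # marker discovery
    min_log2fc: float = 0.58
    max_padj: float = 1e-50
    # GSEA
    gsea_n_perm: int = 2000
    gsea_weight_p: float = 1.0
    gsea_min_size: int = 5
    gsea_max_size: int = 500
    # trajectory orientation anchor (tissue label pinned to positive axis 1)
    anchor_group: str = "mesoderm"
    # single-cell QC
    qc_nmads: float = 3.0
    # single-cell normalization
    sc_target_sum: float = 1e4
    sc_scale_clip: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.max_zero_fraction <= 1):
            raise ValueError("max_zero_fraction must lie in (0, 1]")
        for name in (
            "n_variable_genes", "n_pcs", "knn_k", "louvain_resolution",
            "embed_k", "embed_decay", "embed_t", "embed_n_dims",
            "gsea_n_perm", "gsea_weight_p", "gsea_min_size", "gsea_max_size",
            "qc_nmads", "sc_target_sum", "sc_scale_clip", "min_log2fc",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.max_padj <= 1):
            raise ValueError("max_padj must lie in (0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Derive an independent, reproducible generator for a named stage.

    All stochastic steps in the pipeline draw from generators produced here so
    that re-running a single stage reproduces the full-run result.
    """
    key = zlib.crc32(stream.encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), key]))
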