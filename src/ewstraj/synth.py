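"""Synthetic transcriptome generator with full ground truth.

Emulates the statistical structure the trajectory analysis assumes: a bulk
compendium of tissue groups lying on a latent pluripotent/neuroectodermal to
mesodermal axis, a tumor group whose position on that axis is driven by a
latent fusion-dosage variable d (pseudotime z = 1 - 2d), paired knockdown
experiments that shift dosage, single cells with per-cell dosage
heterogeneity, cell-cycle structure and damaged cells, and gene-set
collections with planted trajectory-correlated sets.

Counts are negative-binomial: counts_gs ~ NB(mean = s_s * exp(eta_gs),
dispersion phi_g) with eta composed of a gene baseline, the trajectory
loading beta_g * z_s, a secondary neuroectoderm loading, tumor-marker
effects, and per-group offsets for off-trajectory ("unrelated") tissues.
Every latent quantity is recorded in :class:`SyntheticTruth` so downstream
recovery can be scored without touching the generator again.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneSetCollection

LN2 = math.log(2.0)

BRANCHES_TRAJECTORY = ("pluripotent", "neuroectoderm", "mesoderm")


class ConfigError(ValueError):
    """Simulation parameters that make downstream tests undefined."""


@dataclass
class SimConfig:
    """Parameters of the bulk-compendium generator.

    Effect sizes are in natural-log units unless the name says log2. Defaults
    give a ~400-sample compendium at 2,000 genes in which the trajectory,
    the tumor markers, and the unrelated tissue groups are all recoverable
    but not trivially separable.
    """

    n_genes: int = 2000
    n_pluripotent: int = 60
    n_neuroectoderm: int = 60
    n_mesoderm: int = 80
    n_tumor: int = 60
    n_unrelated_groups: int = 3
    n_per_unrelated: int = 45
    # gene latents
    baseline_mean: float = 1.0       # mean of mu_g ~ Normal (ln-scale baseline)
    baseline_sd: float = 1.0
    structured_mean: float = 2.2     # baseline for trajectory/marker genes (well expressed)
    structured_sd: float = 0.6
    frac_trajectory: float = 0.30    # genes with nonzero beta_g
    loading_scale: float = 0.8       # sd of beta_g (ln units per unit z)
    frac_secondary: float = 0.10     # genes separating neuroectoderm from pluripotent
    secondary_scale: float = 0.5
    frac_marker: float = 0.05        # tumor marker genes
    marker_effect_log2: float = 1.5  # tumor effect, log2 units
    marker_context_fraction: float = 0.5  # fraction of the marker effect seen in
                                          # on-trajectory normal tissues
    frac_offset_unrelated: float = 0.15   # genes shifted per unrelated group
    offset_scale_unrelated: float = 1.0
    # dispersion phi_g ~ LogNormal(ln(phi_median), phi_log_sd)
    phi_median: float = 0.1
    phi_log_sd: float = 0.5
    # per-sample library-size factor ~ LogNormal(0, libsize_log_sd), plus a
    # weaker per-study shift
    libsize_log_sd: float = 0.3
    study_log_sd: float = 0.1
    n_studies: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pluripotent", "n_neuroectoderm", "n_mesoderm", "n_tumor"):
            if getattr(self, name) < 3:
                raise ConfigError(f"{name} must be >= 3 (downstream tests undefined)")
        if self.n_unrelated_groups and self.n_per_unrelated < 3:
            raise ConfigError("n_per_unrelated must be >= 3")
        for name in ("frac_trajectory", "frac_secondary", "frac_marker",
                     "frac_offset_unrelated", "marker_context_fraction"):
            if not (0 <= getattr(self, name) <= 1):
                raise ConfigError(f"{name} must lie in [0, 1]")
        for name in ("n_genes", "phi_median", "phi_log_sd", "libsize_log_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.loading_scale < 0 or self.marker_effect_log2 < 0:
            raise ConfigError("effect scales must be non-negative")

    @property
    def n_samples(self) -> int:
        return (self.n_pluripotent + self.n_neuroectoderm + self.n_mesoderm
                + self.n_tumor + self.n_unrelated_groups * self.n_per_unrelated)


@dataclass
class SingleCellConfig:
    """Parameters of the single-cell generator (shares gene latents with bulk)."""

    n_cells: int = 1000
    minority_fraction: float = 0.15   # low-dosage (mesenchymal-like) subpopulation
    damaged_fraction: float = 0.05    # high-mito, low-complexity cells
    n_mito_genes: int = 20
    mito_target_fraction: float = 0.05
    damaged_mito_boost: float = 2.2   # ln-units added to mito intensity in damaged cells
    damaged_lib_factor: float = 0.4
    n_phase_genes: int = 50
    phase_elevation: float = 0.7      # ln-units added to phase genes in-phase
    s_fraction: float = 0.20
    g2m_fraction: float = 0.15
    max_phase_trajectory_overlap: float = 0.0
    lib_mean_ln: float = math.log(2000.0)
    lib_log_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 50:
            raise ConfigError("n_cells must be >= 50")
        for name in ("minority_fraction", "damaged_fraction", "s_fraction",
                     "g2m_fraction", "mito_target_fraction"):
            if not (0 <= getattr(self, name) < 1):
                raise ConfigError(f"{name} must lie in [0, 1)")
        if self.s_fraction + self.g2m_fraction >= 1:
            raise ConfigError("phase fractions must sum to < 1")


@dataclass
class SyntheticTruth:
    """Ground-truth latents for simulated samples/cells, genes and gene sets."""

    samples: pd.DataFrame   # index id; columns branch, z, dosage (+ phase/damaged for cells)
    genes: pd.DataFrame     # index gene_id; columns mu, beta, gamma, phi, flags...
    sets: pd.DataFrame | None = None  # index set name; columns planted, direction

    def to_json(self, path) -> None:
        payload = {
            "samples": json.loads(self.samples.to_json(orient="split")),
            "genes": json.loads(self.genes.to_json(orient="split")),
            "sets": None if self.sets is None else json.loads(self.sets.to_json(orient="split")),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())

        def _df(blob):
            if blob is None:
                return None
            df = pd.DataFrame(blob["data"], columns=blob["columns"])
            df.index = pd.Index(blob["index"])
            return df

        return cls(_df(payload["samples"]), _df(payload["genes"]), _df(payload["sets"]))


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Gamma-Poisson draw: NB with var = mean + phi * mean^2 (phi per gene row)."""
    shape = 1.0 / phi[:, None]
    lam = rng.gamma(np.broadcast_to(shape, mean.shape), mean * phi[:, None])
    return rng.poisson(lam).astype(np.int64)


def gene_latents(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-gene latents (baselines, loadings, dispersions, flags).

    Trajectory and marker genes receive the higher "structured" baseline so
    they survive the zero-fraction gene filter at realistic rates, the way
    genuinely informative genes in a compendium are robustly expressed.
    """
    n = cfg.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]
    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, n)
    phi = np.exp(rng.normal(math.log(cfg.phi_median), cfg.phi_log_sd, n))

    n_traj = int(round(cfg.frac_trajectory * n))
    n_sec = int(round(cfg.frac_secondary * n))
    n_marker = int(round(cfg.frac_marker * n))
    perm = rng.permutation(n)
    traj_idx = perm[:n_traj]
    sec_idx = perm[n_traj:n_traj + n_sec]
    marker_idx = perm[n_traj + n_sec:n_traj + n_sec + n_marker]

    beta = np.zeros(n)
    beta[traj_idx] = rng.normal(0.0, cfg.loading_scale, n_traj)
    gamma = np.zeros(n)
    gamma[sec_idx] = rng.normal(0.0, cfg.secondary_scale, n_sec)
    structured = np.zeros(n, dtype=bool)
    structured[np.concatenate([traj_idx, sec_idx, marker_idx])] = True
    mu[structured] = rng.normal(cfg.structured_mean, cfg.structured_sd, structured.sum())

    marker_flag = np.zeros(n, dtype=bool)
    marker_flag[marker_idx] = True

    return pd.DataFrame(
        {
            "mu": mu,
            "beta": beta,
            "gamma": gamma,
            "phi": phi,
            "is_trajectory": np.isin(np.arange(n), traj_idx),
            "is_marker": marker_flag,
            "marker_effect_log2": np.where(marker_flag, cfg.marker_effect_log2, 0.0),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )


def _bulk_eta(cfg: SimConfig, genes: pd.DataFrame, branch: np.ndarray,
              z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per-gene, per-sample log-intensity before library-size scaling."""
    mu = genes["mu"].to_numpy()
    beta = genes["beta"].to_numpy()
    gamma = genes["gamma"].to_numpy()
    m = genes["marker_effect_log2"].to_numpy() * LN2

    zterm = np.where(np.isnan(z), 0.0, z)
    eta = mu[:, None] + beta[:, None] * zterm[None, :]
    eta += gamma[:, None] * (branch == "neuroectoderm")[None, :]
    is_tumor = branch == "tumor"
    on_traj_normal = np.isin(branch, BRANCHES_TRAJECTORY)
    eta += m[:, None] * (is_tumor[None, :] + cfg.marker_context_fraction * on_traj_normal[None, :])

    for g in range(cfg.n_unrelated_groups):
        members = branch == f"unrelated_{g + 1}"
        if not members.any():
            continue
        n_off = int(round(cfg.frac_offset_unrelated * cfg.n_genes))
        off_idx = rng.choice(cfg.n_genes, n_off, replace=False)
        offsets = np.zeros(cfg.n_genes)
        offsets[off_idx] = rng.normal(0.0, cfg.offset_scale_unrelated, n_off)
        eta += offsets[:, None] * members[None, :]
    return eta


def simulate_bulk_compendium(
    cfg: SimConfig, latents: pd.DataFrame | None = None
) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate the bulk tissue compendium.

    Returns the count matrix (genes x samples), observable sample metadata
    (tissue, is_tumor, study, intervention, condition_pair), and the ground
    truth (branch, pseudotime z, tumor dosage d, gene latents).
    """
    rng = np.random.default_rng(cfg.seed)
    genes = gene_latents(cfg, rng) if latents is None else latents

    branches: list[str] = []
    zs: list[float] = []
    ds: list[float] = []
    branches += ["pluripotent"] * cfg.n_pluripotent
    zs += list(rng.uniform(-1.0, -0.55, cfg.n_pluripotent))
    branches += ["neuroectoderm"] * cfg.n_neuroectoderm
    zs += list(rng.uniform(-0.95, -0.35, cfg.n_neuroectoderm))
    branches += ["mesoderm"] * cfg.n_mesoderm
    zs += list(rng.uniform(0.1, 1.0, cfg.n_mesoderm))
    ds += [np.nan] * len(zs)
    d_tumor = rng.uniform(0.5, 1.0, cfg.n_tumor)
    branches += ["tumor"] * cfg.n_tumor
    zs += list(1.0 - 2.0 * d_tumor)
    ds += list(d_tumor)
    for g in range(cfg.n_unrelated_groups):
        branches += [f"unrelated_{g + 1}"] * cfg.n_per_unrelated
        zs += [np.nan] * cfg.n_per_unrelated
        ds += [np.nan] * cfg.n_per_unrelated

    branch = np.array(branches)
    z = np.array(zs)
    d = np.array(ds)
    n = len(branch)
    sample_ids = [f"S{i:04d}" for i in range(n)]

    study = np.array([f"study_{i % cfg.n_studies + 1}" for i in range(n)])
    study_shift = {s: rng.normal(0.0, cfg.study_log_sd) for s in np.unique(study)}
    libsize = np.exp(rng.normal(0.0, cfg.libsize_log_sd, n)
                     + np.array([study_shift[s] for s in study]))

    eta = _bulk_eta(cfg, genes, branch, z, rng)
    mean = np.exp(eta) * libsize[None, :]
    counts = _nb_sample(rng, mean, genes["phi"].to_numpy())

    meta = pd.DataFrame(
        {
            "tissue": np.where(branch == "tumor", "ewing_sarcoma", branch),
            "is_tumor": branch == "tumor",
            "study": study,
            "intervention": "none",
            "condition_pair": "",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth_samples = pd.DataFrame(
        {"branch": branch, "z": z, "dosage": d, "libsize": libsize},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return (
        CountMatrix(list(genes.index), sample_ids, counts),
        meta,
        SyntheticTruth(truth_samples, genes),
    )


def simulate_knockdown(
    cfg: SimConfig,
    n_pairs: int = 6,
    dosage_drop: float = 0.8,
    latents: pd.DataFrame | None = None,
    seed: int | None = None,
) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Paired control/knockdown tumor samples differing only in fusion dosage.

    Each pair shares every latent variable except that the knockdown arm has
    d_kd = d_ctrl * (1 - dosage_drop); with z = 1 - 2d, knockdown moves
    samples toward the mesodermal pole (higher z).
    """
    if n_pairs < 3:
        raise ConfigError("n_pairs must be >= 3")
    if not (0 <= dosage_drop <= 1):
        raise ConfigError("dosage_drop must lie in [0, 1]")
    rng = np.random.default_rng(cfg.seed + 1_000_003 if seed is None else seed)
    genes = gene_latents(cfg, np.random.default_rng(cfg.seed)) if latents is None else latents

    d_ctrl = rng.uniform(0.5, 1.0, n_pairs)
    d_kd = d_ctrl * (1.0 - dosage_drop)
    d = np.concatenate([d_ctrl, d_kd])
    z = 1.0 - 2.0 * d
    n = 2 * n_pairs
    branch = np.array(["tumor"] * n)
    arm = np.array(["control"] * n_pairs + ["knockdown"] * n_pairs)
    pair = np.array([f"pair_{i}" for i in range(n_pairs)] * 2)
    sample_ids = [f"KD{i:03d}_{a}" for i, a in zip(range(n_pairs), ["ctrl"] * n_pairs)] + [
        f"KD{i:03d}_kd" for i in range(n_pairs)
    ]

    # shared per-pair library size; fresh NB noise per arm
    lib_pair = np.exp(rng.normal(0.0, cfg.libsize_log_sd, n_pairs))
    libsize = np.concatenate([lib_pair, lib_pair])
    # marker effect scales with dosage in the knockdown setting
    mu = genes["mu"].to_numpy()
    beta = genes["beta"].to_numpy()
    m = genes["marker_effect_log2"].to_numpy() * LN2
    eta = mu[:, None] + beta[:, None] * z[None, :] + m[:, None] * d[None, :]
    mean = np.exp(eta) * libsize[None, :]
    counts = _nb_sample(rng, mean, genes["phi"].to_numpy())

    meta = pd.DataFrame(
        {
            "tissue": "ewing_sarcoma",
            "is_tumor": True,
            "study": "kd_study",
            "intervention": arm,
            "condition_pair": pair,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth_samples = pd.DataFrame(
        {"branch": branch, "z": z, "dosage": d, "libsize": libsize},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return CountMatrix(list(genes.index), sample_ids, counts), meta, SyntheticTruth(truth_samples, genes)


def simulate_single_cells(
    cfg: SimConfig,
    sc_cfg: SingleCellConfig | None = None,
    latents: pd.DataFrame | None = None,
) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate tumor single cells with dosage heterogeneity and cell cycle.

    The majority of cells carry high fusion dosage; a minority subpopulation
    carries low dosage (mesenchymal-like). Mitochondrial-tagged genes and a
    planted fraction of damaged cells (high mito share, reduced complexity)
    exercise QC; S/G2M phase gene sets with elevated means exercise
    cell-cycle scoring.
    """
    sc = sc_cfg or SingleCellConfig(seed=cfg.seed)
    rng = np.random.default_rng(sc.seed + 7)
    genes = (gene_latents(cfg, np.random.default_rng(cfg.seed)) if latents is None else latents).copy()

    n_genes = len(genes)
    # mito-tagged genes: relabel a block of unstructured genes
    unstructured = np.flatnonzero(
        ~(genes["is_trajectory"] | genes["is_marker"] | (genes["gamma"] != 0))
    )
    if len(unstructured) < sc.n_mito_genes + 2 * sc.n_phase_genes:
        raise ConfigError("not enough unstructured genes for mito and phase sets")
    picks = rng.choice(unstructured, sc.n_mito_genes + 2 * sc.n_phase_genes, replace=False)
    mito_idx = picks[: sc.n_mito_genes]
    s_idx = picks[sc.n_mito_genes: sc.n_mito_genes + sc.n_phase_genes]
    g2m_idx = picks[sc.n_mito_genes + sc.n_phase_genes:]

    overlap = np.mean(genes["is_trajectory"].to_numpy()[np.concatenate([s_idx, g2m_idx])])
    if overlap > sc.max_phase_trajectory_overlap:
        raise ConfigError("phase gene sets overlap trajectory genes beyond configured fraction")

    gene_ids = list(genes.index)
    for j, gi in enumerate(mito_idx):
        gene_ids[gi] = f"MT-{genes.index[gi]}"
    genes.index = pd.Index(gene_ids, name="gene_id")

    mu = genes["mu"].to_numpy().copy()
    # set mito baseline so the expected mito share matches the target
    rel = np.exp(mu)
    non_mito_total = rel.sum() - rel[mito_idx].sum()
    target = sc.mito_target_fraction
    rel_mito_total = non_mito_total * target / (1.0 - target)
    mu[mito_idx] = math.log(rel_mito_total / sc.n_mito_genes)

    n = sc.n_cells
    barcodes = [f"C{i:05d}" for i in range(n)]
    low = rng.random(n) < sc.minority_fraction
    d = np.where(low, rng.uniform(0.0, 0.25, n), rng.uniform(0.6, 1.0, n))
    z = 1.0 - 2.0 * d
    u = rng.random(n)
    phase = np.where(u < sc.s_fraction, "S", np.where(u < sc.s_fraction + sc.g2m_fraction, "G2M", "G1"))
    damaged = rng.random(n) < sc.damaged_fraction

    beta = genes["beta"].to_numpy()
    m = genes["marker_effect_log2"].to_numpy() * LN2
    eta = mu[:, None] + beta[:, None] * z[None, :] + m[:, None] * d[None, :]
    phase_boost = np.zeros((n_genes, n))
    phase_boost[np.ix_(s_idx, np.flatnonzero(phase == "S"))] = sc.phase_elevation
    phase_boost[np.ix_(g2m_idx, np.flatnonzero(phase == "G2M"))] = sc.phase_elevation
    eta += phase_boost
    eta[mito_idx[:, None], np.flatnonzero(damaged)[None, :]] += sc.damaged_mito_boost

    lib = np.exp(rng.normal(sc.lib_mean_ln, sc.lib_log_sd, n))
    lib = np.where(damaged, lib * sc.damaged_lib_factor, lib)
    rel = np.exp(eta)
    p = rel / rel.sum(axis=0, keepdims=True)
    mean = p * lib[None, :]
    counts = _nb_sample(rng, mean, genes["phi"].to_numpy())

    meta = pd.DataFrame(
        {"batch": "cell_line", "tissue": "ewing_sarcoma", "is_tumor": True, "study": "sc"},
        index=pd.Index(barcodes, name="barcode"),
    )
    genes = genes.assign(
        is_mito=np.isin(np.arange(n_genes), mito_idx),
        phase_set=np.select(
            [np.isin(np.arange(n_genes), s_idx), np.isin(np.arange(n_genes), g2m_idx)],
            ["S", "G2M"],
            default="",
        ),
    )
    truth_cells = pd.DataFrame(
        {
            "branch": "tumor",
            "z": z,
            "dosage": d,
            "subpop": np.where(low, "low_dosage", "high_dosage"),
            "phase": phase,
            "damaged": damaged,
            "libsize": lib,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    return CountMatrix(list(genes.index), barcodes, counts), meta, SyntheticTruth(truth_cells, genes)


def phase_gene_sets(truth: SyntheticTruth) -> GeneSetCollection:
    """S / G2M phase sets recorded by the single-cell generator, as a collection."""
    genes = truth.genes
    return GeneSetCollection(
        {
            "S_PHASE": set(genes.index[genes["phase_set"] == "S"]),
            "G2M_PHASE": set(genes.index[genes["phase_set"] == "G2M"]),
        },
        provenance=["synthetic phase sets"],
    )


def simulate_gene_sets(
    truth: SyntheticTruth,
    n_sets: int = 40,
    planted_fraction: float = 0.25,
    set_size: int = 50,
    pool_size: int = 150,
    seed: int = 0,
) -> tuple[GeneSetCollection, pd.DataFrame]:
    """Gene-set collection with planted trajectory-correlated sets.

    Planted sets are sign-coherent draws from the ``pool_size`` genes with the
    most negative (respectively most positive) trajectory loadings; the
    remaining sets are uniform draws from all genes (null sets). Returns the
    collection and a truth table (planted flag, direction in {-1, 0, +1}).
    """
    genes = truth.genes
    if set_size > len(genes):
        raise ConfigError("requested set size exceeds gene count")
    rng = np.random.default_rng(seed)
    n_planted = int(round(planted_fraction * n_sets))
    n_neg = n_planted // 2 + n_planted % 2
    n_pos = n_planted // 2
    order = np.argsort(genes["beta"].to_numpy())
    neg_pool = genes.index.to_numpy()[order[:pool_size]]
    pos_pool = genes.index.to_numpy()[order[-pool_size:]]
    if n_planted and min(len(neg_pool), len(pos_pool)) < set_size:
        raise ConfigError("not enough genes per planted set")

    sets: dict[str, set[str]] = {}
    rows = []
    for i in range(n_neg):
        name = f"PLANTED_NEG_{i:02d}"
        sets[name] = set(rng.choice(neg_pool, set_size, replace=False))
        rows.append((name, True, -1))
    for i in range(n_pos):
        name = f"PLANTED_POS_{i:02d}"
        sets[name] = set(rng.choice(pos_pool, set_size, replace=False))
        rows.append((name, True, 1))
    for i in range(n_sets - n_planted):
        name = f"NULL_SET_{i:03d}"
        sets[name] = set(rng.choice(genes.index.to_numpy(), set_size, replace=False))
        rows.append((name, False, 0))

    set_truth = pd.DataFrame(rows, columns=["name", "planted", "direction"]).set_index("name")
    return GeneSetCollection(sets, provenance=["synthetic collection"]), set_truth
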