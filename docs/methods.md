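# Methods

## The model

The analysis assumes that a fusion-driven tumor's transcriptome lies on a
developmental manifold spanned by normal tissues, and that a single latent
coordinate — pseudotime z ∈ [−1, 1], running from the pluripotent/
neuroectodermal pole (−1) to the mesodermal pole (+1) — captures the
transition of interest. The tumor's position on that axis is controlled by
the expression level ("dosage" d ∈ [0, 1]) of its driver fusion, via
z = 1 − 2d: full fusion dosage pulls cells to the pluripotent-like end,
depleting the fusion releases them toward the mesodermal end. Every stage of
the package either reconstructs this axis from expression data or measures
movement along it.

## Bulk preprocessing

Genes with zero counts in ≥ `max_zero_fraction` (default 10%) of samples are
discarded; the rule is inclusive (a gene at exactly the threshold is
dropped) and idempotent. Size factors are median-of-ratios: for sample j,
s_j = median over genes positive in every sample of count_gj / geomean_g,
rescaled so the factors have geometric mean exactly 1 (that convention makes
the factors scale-equivariant and reproducible to 1e-10). The
variance-stabilizing transform is log2(count / s_j + 1). A fitted
mean–dispersion VST was considered and rejected: every downstream statistic
(medians, Pearson/Spearman correlations, rank tests) depends only on a
monotone variance-stabilizing map, and the log transform keeps the package
dependency-light and the values exactly invertible (2^x − 1), which the
fold-change computation uses. Matrices are held in memory; at the package's
intended scale (10³–10⁴ samples) no chunking is needed.

Variable-gene selection takes the n genes of largest variance with ties
broken lexicographically by gene id; PCA (full SVD) centers genes and fixes
component signs by making the largest-magnitude loading positive, so runs
are bit-reproducible.

## Clustering and marker scoring

The kNN graph uses brute-force Euclidean neighbor search with ties broken by
(distance, sample id) — deterministic by construction — and shared-nearest-
neighbor Jaccard edge weights over the union of directed kNN edges. Louvain
clustering is igraph's multilevel modularity optimization with a seeded node
order.

Tumor markers come from a two-sided Wilcoxon rank-sum test per gene. With
both groups ≤ 8 samples the p-value is computed by exact enumeration of all
assignments (tie-safe); otherwise by a normal-family approximation with tie
correction, continuity correction, and Iman's normal/t blend, which agrees
with the exact p to |Δp| ≤ 0.002 at group sizes 8 (plain normal errs by up
to 0.05 there). Fold change is computed on the pseudo-normalized scale
(2^x − 1 inverts the VST) with pseudocount 1; Bonferroni adjustment across
genes. The default threshold pair mirrors a compendium-scale analysis
(log2FC > 0.58, p_adj < 1e-50). The p threshold deserves a caveat: at a few
hundred samples the Wilcoxon z-statistic is bounded (perfect separation of
100 vs 300 gives p ≈ 7e-51 before multiplicity), so 1e-50 is unattainable
at simulation scale — simulation-scale runs in this package use Bonferroni
0.05, and the configuration records whichever value was used.

The marker score of a sample is the median VST value over the marker genes.
Groups are ranked by median score with all pairwise Welch t-tests under Holm
correction (population-SD "scaled but not centered" column scaling is used
in the tissue-by-cluster composition matrix). For choosing which clusters
enter the trajectory embedding, the significance-based "not significantly
below the leader" rule degenerates at realistic group sizes (every true
difference is significant, leaving only the tumor cluster), so the pipeline
instead splits the sorted cluster medians at the cut minimizing within-group
variance (1-D two-means) and keeps the high group; a `top_k` override
exists. Both the significance rule (in `rank_groups`) and the split rule are
reported.

## Trajectory embedding

The embedding is a diffusion-potential method implemented in-package:

1. pairwise Euclidean distances on the input (PCA scores by default);
2. adaptive bandwidth ε_i = distance to the k-th neighbor (default k = 15);
3. α-decay kernel K_ij = ½[exp(−(d_ij/ε_i)^α) + exp(−(d_ij/ε_j)^α)]
   (default α = 10), with a connectivity check that fails loudly when the
   kernel graph is disconnected;
4. row-normalization to a Markov matrix P, diffusion Pᵗ with fixed t = 40
   (an entropy-based t selection was deliberately not implemented; t is a
   config parameter and the recovery results are flat over a wide t range);
5. potential U = −log(Pᵗ + 1e-7) and classical MDS of the potential
   distances to 2–3 dimensions, with the same deterministic sign convention
   as PCA.

Axis 1 is oriented by negating it if a designated anchor group (mesodermal
tissue by default) has negative mean; the operation is idempotent. Samples
off the tumor-containing trajectory are pruned by clustering the embedding
coordinates (kNN + Louvain) and keeping clusters with any member within
`prune_radius` graph hops (default 3) of a tumor sample. This is an
operationalization of what is inherently a visual judgement; in the
simulation, unrelated tissue groups form disconnected kernel components, so
any finite radius removes them and the radius only controls how aggressively
trajectory stragglers are trimmed (radius 3 retains ≥ 90% of on-trajectory
samples while removing ≥ 90% of unrelated ones across seeds).

## Gene scores, intervention tests, enrichment

The trajectory gene score is signed R²: sign(r)·r² of the Pearson
correlation between a gene's median-of-ratios-normalized log2 expression and
the axis-1 coordinate over a stated subset (all embedded samples, normals
only, or tumors only). Whether to correlate on log or linear scale is not
dictated by the statistic; log scale is used because it matches the
variance-stabilized space in which every other statistic operates, and the
choice is recorded in the output's transform tag. Genes constant on the
subset are flagged undefined and excluded from rankings rather than scored
zero — scoring them zero would fabricate a tie block at the center of the
GSEA ranking. Threshold gene sets use strict inequality ("score < −0.2"
excludes a gene at exactly −0.2). Intervention shifts are Welch t-tests on
axis-1 coordinates, one-tailed (treatment higher) for fusion knockdown,
two-sided otherwise.

Preranked GSEA uses the weighted KS running sum (hit increments ∝ |score|^p
with p = 1, miss decrements 1/(N − N_hit)); the extremum is computed in
closed form at the hit boundaries of the piecewise-linear running sum, which
lets the permutation null (gene-label permutation — the only scheme
available for preranked input) be evaluated vectorized with one shared draw
per set size. p = (1 + #{same-sign permuted ES at least as extreme}) /
(1 + #{same-sign permuted ES}); NES divides ES by the mean |permuted ES| of
the same sign. Sets smaller than 5 or larger than 500 within the ranking,
or spanning the whole list, are skipped. ORA is the upper-tail
hypergeometric test (scipy's survival function; verified against direct
summation to 1e-12), with the post-filter gene universe as the default
background. Both adjust across sets by Benjamini–Hochberg. The overlap of
two enrichment results is itself tested hypergeometrically with the
collection as universe; the significance level for "shared" sets defaults
to BH 0.05 and is configurable.

## Single-cell projection

QC removes cells outside median ± 3 MAD (MAD scaled by 1.4826) on log UMIs
and log detected genes, or above median + 3 MAD on percent-mitochondrial
counts; thresholds are overridable and logged, and the filter refuses to
proceed if it would remove > 90% of cells (the usual symptom of a wrong
mito tag). Normalization is log2(1 + count/total × 10⁴) followed by
per-gene z-scoring clipped at ±10. Cell-cycle scores are module scores —
mean over phase genes minus mean over expression-bin-matched control genes
(25 bins, 50 seeded controls per gene) — computed on the unscaled
log-normalized matrix; a cell is called S or G2M by arg-max if the best
score is positive, else G1.

The per-cell trajectory score multiplies the scaled expression values by
the bulk signed-R² weights and takes the median over the cell's multiset of
genes with raw count > 0 and a defined, non-zero weight. "Non-zero weighted
gene counts" is ambiguous between "genes the cell expresses" and "values
that happen to be non-zero after weighting"; the former is implemented
(raw count > 0 AND weight ≠ 0) because scaled values can vanish by
numerical accident and zero-weight genes carry no information. Cells whose
multiset is empty are flagged missing, not scored 0. Scaled (signed) values
are used as the quoted procedure states; the unscaled variant can be
obtained by passing the log-normalized matrix instead. Clusters are ranked
by median score with quartiles reported; per-cluster one-vs-rest markers
(both directions, disjoint by construction) feed separate ORA runs for
positive and negative markers. Cross-batch anchor integration is out of
scope; batches are analyzed jointly with the batch label recorded.

## The synthetic-data generator

Counts are negative-binomial (gamma–Poisson), counts_gs ~ NB(mean =
s_s·exp(η_gs), dispersion φ_g), with gene-specific dispersions drawn
log-normal (median 0.1, log-SD 0.5) — realistic heteroscedasticity that the
VST stage must handle — and per-sample library factors log-normal (log-SD
0.3) plus a weaker per-study shift (log-SD 0.1). No zero inflation beyond
NB sampling is added, matching the analysis's assumptions. η combines: a
baseline μ_g (Normal(1, 1) in ln units; trajectory/marker genes draw from
Normal(2.2, 0.6) because genuinely informative compendium genes are
robustly expressed — and because genes too shallow to survive the zero
filter cannot carry recoverable signal); trajectory loadings β_g
(Normal(0, 0.8) for a 30% gene fraction) times pseudotime z; a weaker
secondary loading separating neuroectoderm from pluripotent tissue (the
branch geometry is encoded this way, as a scalar z plus branch labels,
because axis-1 recovery is the only quantitative claim the analysis makes);
tumor-marker effects m_g (1.5 log2 on a 5% gene fraction) in tumor samples,
with half that effect in on-trajectory normal tissues — markers of a
developmental tumor are expressed in its developmental context, and without
this the context tissues could never outrank unrelated tissues in marker
score, leaving nothing for the embedding stage to select; and per-group
offsets (Normal(0, 1) on 15% of genes) for each unrelated tissue group.

Group pseudotimes: pluripotent U(−1, −0.55), neuroectoderm U(−0.95, −0.35),
mesoderm U(0.1, 1), tumor z = 1 − 2d with d ~ U(0.5, 1); unrelated groups
have undefined z (the loading term is dropped). Knockdown simulation copies
all pair latents and sets d_kd = d_ctrl·(1 − drop), with marker effects
scaling with dosage. Single cells share the bulk gene latents, draw
per-cell dosage from a high-dosage majority (d ~ U(0.6, 1)) and a
low-dosage minority (15%, d ~ U(0, 0.25)), multinomial-like gene
proportions scaled to log-normal library sizes (~2,000 UMIs), 20
mitochondria-tagged genes calibrated to a 5% expected mito share, a 5%
damaged-cell fraction (mito intensity ×e^2.2, library ×0.4), and S/G2M
phase sets (50 genes each, disjoint from trajectory genes) elevated by 0.7
ln units in-phase. Gene-set collections plant sign-coherent sets drawn from
the 150 most extreme loadings; the rest are uniform null sets.

What the generator does **not** emulate: batch effects beyond library-size
shifts, ambient RNA and doublets, gene–gene correlation beyond the shared
latent factors, realistic gene identities or set sizes, and tree-structured
branching. Passing recovery tests therefore demonstrates that the
implementation recovers the structure its model class assumes — not that
the method is robust to the full messiness of real compendia.

## Recovery studies and problem sizes

`ewstraj.workflows` wires the stages into recovery recipes used by the test
suite, the examples, and `scripts/acceptance.py`: the default bulk chain
(395 samples × 2,000 genes; ~1,300 genes after filtering), marker recovery
at 100 tumor vs 300 rest with a context-rich rest (75 samples each of
pluripotent, neuroectodermal, mesodermal, and one unrelated group — a
balanced background separates the marker mechanism from the tumor group's
trajectory position, which otherwise makes the most extreme trajectory
genes look like markers), knockdown shift with 6 pairs at an 80% dosage
drop embedded jointly with the compendium, GSEA recovery with 40 sets (10
planted per sign) at 2,000 permutations plus a 200-null-set calibration
run, and a 1,000-cell projection study. These sizes keep the full suite
under a minute per study while leaving comfortable statistical margins;
they are stated here because every reported number depends on them.

## Numerical and degenerate-case choices

Constant genes: p = 1 and log2FC = 0 in marker tests (not an error),
undefined in trajectory scores, zero after scaling in the single-cell path.
Zero-variance composition columns are left unscaled with a warning.
Size-factor estimation refuses matrices with no gene positive everywhere
and points at the gene filter. PCA requests beyond the rank truncate with a
warning; kNN k must be < n; the embedding refuses disconnected kernels
rather than silently embedding components independently. All randomness
flows from named, crc32-keyed child streams of one seed (`stream_rng`), so
re-running a single stage reproduces the full-run result, and two runs with
the same config and seed produce byte-identical outputs.
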