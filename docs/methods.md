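# Methods

This note records the models, conventions and numerical choices behind
`molgrad`, and what the synthetic-cohort tests do and do not establish
about real data.

## Inter-regional covariance (IRCA)

The covariance network of a modality is the cross-subject Pearson
correlation of parcel values. Decisions:

- **Outlier fences.** Box-plot rule with strict inequalities
  (`x < Q1 − 1.5·IQR` or `x > Q3 + 1.5·IQR`), quartiles by linear
  interpolation (type 7) — the most common convention, declared so fences
  are reproducible. Stratification is age decade ([20,30) … [70,80], the
  upper edge closed) crossed with sex; strata under 4 subjects merge into
  the neighboring decade of the same sex because fences are unstable below
  n = 4. Imputation replaces a flagged cell with the mean of non-flagged
  subjects in the same age decade at the same parcel (parcel identity
  already fixes the hemisphere; sexes are pooled within decade).
- **Confound model.** Per-parcel OLS on `[1, age_c, age_c², sex]` with age
  centered in years. The age-preserved control is per-parcel z-scoring
  (identical to plain correlation). The "age-attributable dissimilarity"
  between the two matrices is defined here as `1 − R²` of the edgewise
  least-squares fit over strictly-upper-triangle edges; the edge rank
  agreement is Spearman's rho on the same edges.
- Degenerate (zero-variance) parcels are an error, detected with a
  relative tolerance of `1e−12·(1 + |mean|)` because constant columns
  leave O(eps) float residue in a standard deviation.

## Functional graphs

Subject graphs are Pearson correlations of parcel time series with
`artanh` variance stabilization; correlations are clipped to
±(1 − 1e−7) first so a duplicated region cannot contribute an infinite
edge to group means. The group graph is the edgewise mean of z values
mapped through `tanh`, restoring the (−1, 1) range before thresholding
and decomposition.

## Gradients

- **Thresholding** keeps, per row, the `ceil(density·(P−1))` largest
  strictly positive off-diagonal entries (default density 0.10), ties at
  the cutoff resolved toward the lower parcel index; negative edges are
  zeroed. The thresholded matrix is left asymmetric: each row is one
  parcel's trimmed connectivity profile.
- **Affinity** is the normalized angle between row profiles, in [0, 1]
  with unit diagonal. All-zero rows are an error (no direction).
- **Embedding** solves the symmetric normalized Laplacian
  `L = I − D^(−1/2) W D^(−1/2)` densely (P ≤ a few thousand), takes the k
  smallest nonzero eigenvalues (default k = 10; analyses use the first 4),
  back-transforms eigenvectors by `D^(−1/2)` (random-walk convention), and
  discards the constant eigenvector. Connectivity of the affinity graph is
  checked (union of row supports); a disconnected graph is an error, never
  silently densified. Column signs are fixed so the largest-magnitude
  entry is positive; after Procrustes alignment the target's convention
  governs.
- **Variance explained** is the transition-operator eigenvalue share
  `(1 − λᵢ)/Σⱼ(1 − λⱼ)` over retained components: nonincreasing and
  summing to one for affinity-scale inputs (for exotic graphs with
  λ > 1 the shares remain well defined but can be negative).
- **Alignment** is classical orthogonal Procrustes (closed form via SVD),
  no scaling or translation, so all pairwise embedding distances are
  preserved; signed permutations are recovered exactly.
- **Correlation differences** between two r values use the two-sample
  Fisher-z test for independent samples and Steiger's Z (shared-variable
  case, requiring the overlap correlation) for dependent ones. Both the
  parcel-based and subject-based sample sizes are the caller's choice;
  the functions take n explicitly.

## Spin inference

Null maps are built by rotating the spherical parcel projection: one
Haar-uniform rotation per permutation applied to the left hemisphere and
its x-mirror to the right, so bilateral symmetry is respected and
assignments never cross hemispheres. Two matching conventions are
provided:

- `nearest` (default): each rotated parcel takes the value of the nearest
  original parcel; duplicates permitted. Well calibrated for map-level
  statistics (measured type-I ≈ 0.04–0.06 at α = 0.05 on smooth isotropic
  nulls).
- `assignment`: rotated parcels are matched one-to-one by optimal
  assignment on spherical distance, so every spin is a true permutation.
  This is the convention used for matrix-level statistics, where
  duplicated parcels would shrink the effective parcel count under
  rotation and inflate the null variance — with duplicates the matrix
  test is grossly conservative (measured type-I ≈ 0.003). Any remaining
  duplicate-pair edge cells (possible only with `nearest` spins) are
  excluded from spun statistics via NaN masking.

P-values use the `(1 + #extreme)/(1 + n_perm)` rule (never zero);
two-tailed tests compare absolute deviations from the null mean. Matrix
spins exploit an exact identity: the Pearson correlation matrix of
column-permuted data is the reindexed matrix `C[a][:, a]`, so adjacencies
under rotation are obtained without recomputing correlations (verified
against naive recomputation in the tests).

Known limitation: one-tailed matrix-level spin tests develop a mild
anticonservative skew as the parcel count and subject count grow
(assignment matching slightly degrades map smoothness at band
boundaries; ~13% null rejections at P = 200 with 100 subjects versus ~7%
at P = 100). Calibration studies and the modularity-detection check are
therefore run at P = 100. Parcel-level spins of strongly anisotropic
(single-axis) maps are also intrinsically weak: two maps that both follow
the same global axis can yield unremarkable spin p-values despite high
correlation.

## Network and edgewise statistics

- Network centers of mass are medians (even counts: mean of the middle
  two). Hierarchy scores are plain Pearson correlations between a
  subject's map and a reference gradient; the reference can be the group
  gradient (template projection) or each subject's own aligned gradient —
  the pipeline embeds subjects individually and aligns them to the group
  template by Procrustes.
- Position regressions are per-network OLS on
  `[1, score, age, sex, FD]`; the score term's p-values are
  Benjamini–Hochberg corrected across the seven networks.
- Partial Spearman correlations rank-transform *all* variables (the two
  edge vectors and every covariate edge set), then residualize the x/y
  ranks on the centered covariate ranks and correlate the residuals
  (rank-then-residualize; with ties this differs from
  residualize-then-rank, hence declared). Distance covariates enter as
  centered `[d, d²]`. Residuals whose norm is at float-noise scale are
  treated as exactly zero.
- `match_threshold` removes weakest edges first until the retained mean
  reaches the target (verified against exhaustive search); receptor
  similarity is a weighted Pearson correlation of z-scored receptor
  profiles with equal weights by default.
- Mediation: path a from `m ~ x`, path b and the direct effect from
  `y ~ x + m`, all after residualizing on covariates;
  Sobel `z = ab/√(b²SEₐ² + a²SE_b²)` with a two-tailed normal p.
  The outcome R² is decomposed into unique(x), unique(m) and shared parts
  that sum to the full-model R² by construction (commonality analysis);
  nested-model F comparisons are available through the same OLS
  machinery.

## The synthetic cohort

The generator emulates an adult-lifespan molecular-imaging study: 176
subjects aged 20–78 (stratified by decade, half female), 400 parcels in
two mirror-symmetric hemispheres with seven spatially contiguous network
bands, receptor maps, cortical thickness, and BOLD runs. Default
parameters (units are standard deviations of the standardized planted
axis unless noted):

| parameter | default | meaning |
|---|---|---|
| hierarchy_mean / sd | 0.6 / 0.4 | per-subject hierarchy coefficient h_s |
| mean_template_slope | 0.3 | group-mean map's loading on the axis |
| noise_sd | 1.0 | white residual of receptor maps |
| spatial_noise_sd / scale | 0.2 / 0.3 | smooth residual field (chord-distance Gaussian kernel) |
| receptor_network_sd | 0.25 | per-subject network factors |
| network_strengths | 0.6–1.35 | network coherence, sensory → associative |
| hub_spread | 0.5 | per-parcel loading spread, shared with BOLD |
| modularity | 0.15 | BOLD modular loading scale |
| bold_axis_strength | 1.4 | BOLD axis-chain factor scale |
| n_timepoints | 240 | BOLD samples per subject |
| thickness_loading / share | 0.4 / 0.6 | thickness loading on the shared structure; overlap of its network factors and hubs |

Structural choices worth stating:

- **Smooth residuals.** Receptor maps carry a spatially autocorrelated
  residual component in addition to white noise. Without it, spin tests
  are degenerate (nothing to preserve) and the covariance structure
  collapses to an exact two-block sign pattern of the axis instead of a
  graded gradient. Setting `spatial_noise_sd = 0` recovers the pure
  white-noise model (used by the rank-1 limit tests).
- **BOLD structure.** Parcel loadings form a chain of Gaussian bumps along
  the planted axis, so connectivity profiles decay continuously with
  hierarchy distance and the leading functional gradient is monotone in
  the axis; network factors add modular contrast. The modularity default
  keeps the strongest network's loading below the regime where block
  structure, rather than the axis, dominates the first eigenvector.
- **Hierarchy recovery.** A subject's hierarchy score is a correlation,
  which saturates in its argument; the h_s distribution is placed in the
  quasi-linear regime so scores are informative. At the defaults the
  group covariance gradient recovers the planted axis at |Spearman| ≈
  0.97 and scores recover h_s at r ≈ 0.9 (both recomputed by
  `scripts/acceptance.py`).
- **What the cohort does not plant.** No coupling between h_s and network
  positions (the Laplacian embedding is scale-invariant, so uniform
  per-subject axis gain cannot move median positions; the position
  regression's calibration and power are demonstrated with a direct
  position generator instead, and the cohort-level regression is an
  honest null). Thickness covariance shares the axis and part of the
  modular structure, so in this cohort its mediation of the receptor–FC
  association is close to complete — the mediation routine's partial- and
  full-mediation behaviors are exercised with controlled generators in
  the tests. BOLD noise is white (all downstream statistics are spatial);
  no hemodynamics, motion artifacts or volumetric images.

Passing tests on this cohort establish that the estimators recover
planted structure of realistic strength under realistic spatial
autocorrelation; they do not establish robustness to artifacts the
generator omits (motion, physiological noise, parcellation error,
partial-volume effects).

## Problem sizes and determinism

The test suite runs calibration studies at P = 100 with 500
replicates x 500 spins, detection checks at P = 100–200 with 199 spins
and 20 replicates, and planted-recovery checks at the full 400-parcel,
176-subject scale; `scripts/acceptance.py` uses the full scale with
1,000 spins. A single seed fans out to per-stage seeds by fixed offsets;
identical config + seed reproduces every output byte for byte (TSV
floats are formatted, JSON keys sorted, manifests carry content hashes).
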