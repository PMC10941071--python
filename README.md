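# molgrad

Molecular covariance networks and connectome gradients at parcel
resolution.

`molgrad` implements a complete analysis chain for asking how the cortical
organization of a PET-imaged receptor system (the motivating case is the
dopamine D1 receptor, indexed by its nondisplaceable binding potential
BP_ND) relates to the functional architecture of the brain measured with
resting-state fMRI. It is written for imaging neuroscientists who work
with parcel-level data: everything operates on subjects x parcels tables,
parcels x parcels graphs, and a parcel atlas with spherical coordinates
and seven canonical network labels.

## What it computes

**Inter-regional correlation analysis (IRCA).** Correlating a regional
measure across subjects yields a P x P covariance network
`A[p,q] = corr_s(x_s[p], x_s[q])`. Before correlating, univariate
outliers are fenced per age-decade x sex stratum (box-plot rule,
1.5 x IQR, type-7 quartiles) and imputed from age-matched peers, and
linear + quadratic age and sex effects are removed by per-parcel least
squares. An age-preserved control (per-parcel z-scoring only) and an
edgewise matrix comparison (Spearman rho; 1 − R² dissimilarity fraction)
are included.

**Functional graphs.** Subject connectivity is Pearson correlation of
parcel BOLD series, Fisher-z transformed (`artanh`), averaged across
subjects, and mapped back to (−1, 1) by `tanh` for decomposition.

**Gradients.** A connectivity matrix is row-thresholded to its top 10%
positive edges, converted to a normalized-angle affinity
`a(i,j) = 1 − arccos(cos_sim(row_i, row_j))/π`, and decomposed via the
graph Laplacian `L = I − D^(−1/2) W D^(−1/2)`: the eigenvectors of the k
smallest nonzero eigenvalues, back-transformed by `D^(−1/2)`, are the
*gradients* — continuous axes of connectivity-profile similarity.
Embeddings from different modalities are aligned by orthogonal Procrustes
rotation, which resolves eigenvector order and sign without distorting
the manifold.

**Spin inference.** Parcel maps live on a registration sphere; rotating
the sphere (mirrored across hemispheres) and re-matching rotated parcels
to original parcels produces null maps that preserve spatial
autocorrelation. Map-level tests (spatial correlations) and matrix-level
tests (statistics of re-derived covariance matrices) use these spins with
the `(1 + #extreme)/(1 + n_perm)` p-value rule.

**Network and edgewise statistics.** Network centers of mass (median
gradient value), subject hierarchy scores (spatial correlation of a
subject's receptor map with a reference gradient), nuisance-adjusted
network-position regressions with Benjamini–Hochberg FDR, within/between
network covariance summaries, nodal density ANOVA, distance-controlled
partial Spearman correlations of edges, receptor-similarity matrices,
threshold matching, and Sobel mediation with commonality analysis.

**Synthetic cohorts.** Because subject-level PET/fMRI data of this kind
are not publicly distributable, `molgrad` ships a seeded generator that
plants a known unimodal–transmodal axis, per-subject hierarchy strength,
age and sex effects, network-modular covariance, and latent-factor BOLD
structure — every downstream claim is tested against this ground truth.

## A worked example

```python
import molgrad as mg

atlas  = mg.make_atlas(200, seed=1)
cohort = mg.simulate_cohort(mg.CohortSpec(n_subjects=100, n_timepoints=1,
                                          seed=3), atlas)

mask  = mg.detect_outliers(cohort.d1dr)
clean = mg.impute_outliers(cohort.d1dr, mask)
adj   = mg.irca_matrix(clean, residualize_first=True)
gs    = mg.adjacency_gradients(adj, density=0.10, k=10)

rho = mg.spatial_corr(gs.gradient(0), cohort.truth["gradient_template"])
```

Running `python examples/02_receptor_covariance_gradients.py` (which is
this example with reporting) prints:

```
outlier cells flagged: 875 (4.38% of cells)
age-preserved vs age-regressed covariance: Spearman rho = 0.968, age-attributable variance = 6.0%
variance explained by first 4 gradients: 68.7% (2 gradients cover >50%)
gradient 1 vs planted template: Spearman rho = -0.964
```

The last line is the point: the leading gradient of the receptor
covariance network recovers the planted unimodal–transmodal axis (sign is
arbitrary for an eigenvector). The `examples/` directory holds one short
script per capability: cohort simulation, covariance gradients, cross-
modal alignment with spin tests, network positions, and edgewise
coupling/mediation.

A thin CLI mirrors the library for shell use:
`molgrad simulate|irca|fc|gradients|spin|networks|run|validate` — see
`molgrad --help`. `molgrad run` executes the whole pipeline from a YAML
config with a single seed and writes a manifest of content hashes;
rerunning with the same config and seed reproduces every output byte for
byte.

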