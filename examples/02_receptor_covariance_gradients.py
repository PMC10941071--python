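"""Inter-regional receptor covariance and its gradient decomposition.

Runs the molecular arm of the pipeline: outlier fencing and imputation,
confound residualization, the cross-subject correlation matrix (IRCA), and
Laplacian-eigenmap gradients; then checks the leading gradient against the
planted hierarchy template.
"""

import numpy as np

import molgrad as mg

atlas = mg.make_atlas(200, seed=1)
cohort = mg.simulate_cohort(mg.CohortSpec(n_subjects=100, n_timepoints=1,
                                          seed=3), atlas)

mask = mg.detect_outliers(cohort.d1dr)
clean = mg.impute_outliers(cohort.d1dr, mask)
print(f"outlier cells flagged: {mask.sum()} "
      f"({100 * mask.mean():.2f}% of cells)")

adj = mg.irca_matrix(clean, residualize_first=True)
raw = mg.irca_matrix(clean, residualize_first=False)
cmp = mg.compare_matrices(raw, adj)
print(f"age-preserved vs age-regressed covariance: "
      f"Spearman rho = {cmp.spearman_rho:.3f}, "
      f"age-attributable variance = "
      f"{100 * cmp.dissimilarity_variance_fraction:.1f}%")

gs = mg.adjacency_gradients(adj, density=0.10, k=10)
frac, k_half = mg.variance_profile(gs, cumulative_threshold=0.5)
print(f"variance explained by first 4 gradients: {100 * frac[:4].sum():.1f}% "
      f"({k_half} gradients cover >50%)")

rho = mg.spatial_corr(gs.gradient(0), cohort.truth["gradient_template"])
print(f"gradient 1 vs planted template: Spearman rho = {rho:.3f}")
# |rho| near 1 means the embedding recovered the planted
# unimodal-transmodal axis from the covariance structure alone.
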