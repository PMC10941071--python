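"""Simulate a synthetic PET + fMRI cohort with a planted cortical hierarchy.

Builds a bilateral 100-parcel atlas, simulates 40 subjects with the default
planted unimodal-transmodal receptor axis, and prints what was planted.
"""

import numpy as np

import molgrad as mg

atlas = mg.make_atlas(100, seed=1)
spec = mg.CohortSpec(n_subjects=40, n_timepoints=120, seed=7)
cohort = mg.simulate_cohort(spec, atlas)

print(f"atlas: {atlas.n_parcels} parcels, "
      f"{(atlas.hemisphere == 'L').sum()} per hemisphere")
print(f"receptor matrix: {cohort.d1dr.values.shape} (subjects x parcels)")
print(f"BOLD runs: {len(cohort.timeseries)} subjects x "
      f"{cohort.timeseries['sub-0000'].shape} (parcels x timepoints)")
print(f"ages: {cohort.covariates['age'].min():.0f}-"
      f"{cohort.covariates['age'].max():.0f} years")
h = cohort.truth["h"]
print(f"planted hierarchy coefficients h_s: mean {h.mean():.2f}, sd {h.std():.2f}")
# h_s scales how strongly each subject's receptor map follows the planted
# unimodal-transmodal template; downstream analyses try to recover it.
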