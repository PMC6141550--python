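"""Family-aware association between personality profiles and mode engagement.

Plants a coupling of strength rho=0.4 between profile 5's subject loading
and mode 2's engagement, runs the full estimate path (both ICAs +
engagement), and tests all 5 x 12 profile-mode cells with gender-corrected
partial correlations, Freedman-Lane permutations restricted to family
blocks, and Benjamini-Hochberg FDR across the 60 tests.
"""

import numpy as np

from icalink import (
    derive_profiles,
    derive_temporal_modes,
    engagement_from_set,
    gender_covariate,
    match_components,
    run_association,
    simulate_study,
    SimulationConfig,
)
from icalink.synthetic import random_ground_truth

cfg = SimulationConfig(n_subjects=300, n_timepoints=200, seed=2, neo_scale=False)
truth = random_ground_truth(seed=2, coupling_pairs=[(4, 1, 0.4)])
table, ts, families, _ = simulate_study(cfg, truth)
print(f"{cfg.n_subjects} subjects in {len(families.blocks())} family blocks "
      f"({families.zygosity.count('MZ')} MZ and {families.zygosity.count('DZ')} "
      f"DZ twins); permutations never split a family.")

profiles, loadings = derive_profiles(table, seed=0)
modes = derive_temporal_modes(ts, seed=0)
engagement = engagement_from_set(ts, modes)

result = run_association(
    engagement, loadings, gender_covariate(table), families,
    n_perm=2000, seed=0,
)

frame = result.to_frame()
print("\nSignificant profile-mode cells (BH q < 0.05 over 60 tests):")
print(frame.query("significant").to_string(index=False))

# where did the planted coupling land in estimated component space?
raw_sd = np.sqrt((truth.profile_mixing**2).sum(axis=1) + cfg.noise_sd_personality**2)
perm_p, _, _ = match_components(truth.profile_mixing / raw_sd[:, None], profiles.weights.T)
perm_m, _, _ = match_components(truth.spatial_mixing, modes.spatial_weights.T)
k, m = perm_p[4], perm_m[1]
print(f"\nPlanted coupling (true profile 5 -> true mode 2) maps to estimated "
      f"cell (profile {k + 1}, mode {m + 1}): r = {result.r[k, m]:+.3f}, "
      f"FDR-adjusted p = {result.p_adjusted[k, m]:.4f}")
print("The |r| is the gender-corrected partial correlation; its magnitude "
      "tracks the planted rho = 0.4 after estimation attenuation.")
print("Smaller negative cells in the same profile row are compensatory: "
      "per-subject variance normalization makes a loud mode depress the "
      "estimated engagement of every other mode (see docs/methods.md).")
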