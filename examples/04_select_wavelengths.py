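"""Characteristic-wavelength selection on a planted-band cohort.

The planted cohort hides five ash-sensitive bands and one ash-insensitive
decoy among 200 variables; a good selector finds all five informative
neighborhoods and drops the decoy.
"""
import numpy as np

from thzash import CarsConfig, boss, cars, planted_cohort, spa

X, y, info_bands, decoy = planted_cohort(seed=3)
centers = [b[len(b) // 2] for b in info_bands]
print(f"planted: 5 informative bands at {centers}, decoy near {decoy[len(decoy)//2]}")

res = cars(X, y, CarsConfig(n_runs=50, seed=3))
hit = sum(bool(np.intersect1d(res.chosen, b).size) for b in info_bands)
print(f"CARS: {res.chosen.size} variables, {hit}/5 bands hit, "
      f"decoy included: {bool(np.intersect1d(res.chosen, decoy).size)}, "
      f"best RMSECV {res.rmsecv_trace.min():.4f} at run {res.best_iteration}")

res_b = boss(X, y, max_lv=10, n_iterations=15, n_bootstrap_models=50,
             cv_folds=5, seed=3)
hit_b = sum(bool(np.intersect1d(res_b.chosen, b).size) for b in info_bands)
print(f"BOSS: {res_b.chosen.size} variables, {hit_b}/5 bands hit "
      "(soft shrinkage keeps more variables than CARS)")

# SPA on the screened region (it ranks variables by projection norm, so the
# noisy high-index region must be excluded first)
res_s = spa(X[:, :170], y, 1, 12, cv_folds=5)
print(f"SPA: {res_s.chosen.size} variables chosen -> {list(res_s.chosen)}")
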