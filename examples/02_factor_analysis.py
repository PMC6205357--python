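"""Reduce a 17-measure behavioral battery to orthogonal deficit factors.

Simulates a cohort whose battery has 3 planted factors, fits PCA with
varimax rotation under the Kaiser retention rule, and checks how well the
planted loading structure is recovered.
"""

import numpy as np

from lesionkit import simulate as sim
from lesionkit.factors import align_factors, fit_pca_varimax, tucker_congruence

cohort, truth = sim.simulate_cohort(sim.battery_scenario(seed=1))
cols = [c for c in cohort.behavior.columns if c.startswith("measure")]
battery = cohort.behavior[cols]

model = fit_pca_varimax(battery, n_factors="kaiser")
print(f"measures: {len(cols)}, retained factors (eigenvalue > 1): {model.n_factors}")
print("top eigenvalues:", np.round(model.eigenvalues[:5], 2))
print("variance explained per rotated factor:",
      np.round(model.variance_explained, 3),
      f"(total {model.variance_explained.sum():.1%})")

aligned, _, _ = align_factors(model.loadings, truth.battery_loadings)
cong = np.diag(tucker_congruence(aligned, truth.battery_loadings))
print("Tucker congruence with planted loadings:", np.round(cong, 3))
print("-> congruence > 0.95 per factor means the rotated components are the")
print("   planted deficit dimensions; factor scores feed the mapping stages.")
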