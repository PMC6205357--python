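"""Mass-univariate VLSM with generalized permutation FWER correction.

Maps a focal deficit voxel by voxel on the dTLVC-normalized lesion matrix,
thresholds with the permutation-based order-v FWER rule, and compares the
surviving template with the planted critical region.
"""

import numpy as np

import lesionkit as lk
from lesionkit import simulate as sim
from lesionkit.experiments import dice
from lesionkit.vlsm import continuous_fwer_threshold, vlsm_template

cohort, truth = sim.simulate_cohort(sim.focal_scenario(seed=1))
mask = lk.build_analysis_mask(cohort)
X = lk.dtlvc_normalize(cohort, mask)
y = cohort.behavior["focal_deficit"].to_numpy()

sm = continuous_fwer_threshold(X, y, B=1000, v=100, alpha=0.05,
                               rng=np.random.default_rng(0))
tpl = vlsm_template(sm)
region = truth.critical_regions["focal_deficit"]

print(f"in-mask voxels: {mask.n_voxels}")
print(f"effective FWER order v_eff = {sm.params['v_eff']} "
      f"(v=100 rescaled to this mask size)")
print(f"critical value (on -t scale): {sm.threshold:.3f}")
print(f"surviving voxels: {tpl.size}")
print(f"Dice overlap with planted region: {dice(tpl.voxels, region):.2f}")
print("-> the correction bounds the chance of >= v_eff false-positive voxels")
print("   at 5%; survivors concentrate on and around the planted region.")
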