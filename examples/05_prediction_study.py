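"""Does lesion location predict deficits beyond lesion size?

Runs the full 8-fold cross-validated pipeline for a focal and a size-driven
deficit: per fold, LSM templates are trained on 7/8 of the cohort, held-out
template lesion loads are computed, and nested regressions compare
size-only vs size+load models.
"""

from lesionkit import simulate as sim
from lesionkit.predict import run_study2

cfg = sim.ScenarioConfig(
    n_participants=128,
    deficit_models={
        "focal": sim.DeficitModel(w_focal=1.0, critical_center=(12, 21, 16),
                                  noise_sd=1.0),
        "size": sim.DeficitModel(w_size=1.0, noise_sd=1.0),
    },
    seed=7,
)
cohort, _ = sim.simulate_cohort(cfg)
deficits = {k: cohort.behavior[k].to_numpy() for k in ("focal", "size")}

result = run_study2(cohort, deficits, seed=7)
print(result.summary()[
    ["deficit", "method", "r2_size", "r2_load", "r2_both",
     "delta_r2", "p_value", "significant"]
].round(3).to_string(index=False))
print()
print("optimized sparseness per deficit:", result.sparseness)
print("-> for the focal deficit, adding template lesion load to a size-only")
print("   model raises R^2 substantially (significant delta R^2); for the")
print("   size-driven deficit, location adds nothing beyond lesion size.")
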