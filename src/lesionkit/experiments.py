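"""Canned validation experiments on synthetic cohorts.

Each function runs one end-to-end property experiment of the pipeline on
simulated ground-truth cohorts and returns summary numbers: null
calibration of the generalized FWER correction, planted-region recovery,
sparseness adaptivity of the sparse mapper, the size/location dissociation
of the prediction pipeline, the behavior-side size control, and factor
recovery.  They are used by the test suite and by ``scripts/acceptance.py``;
replicate counts are arguments so callers can trade precision for runtime.
"""

from __future__ import annotations

import numpy as np

from . import simulate as sim
from .cohort import build_analysis_mask, dtlvc_normalize
from .factors import align_factors, fit_pca_varimax, tucker_congruence
from .predict import behavior_residual_control, run_study2
from .sccan import optimize_sparseness, sccan_fit, sccan_template
from .vlsm import continuous_fwer_threshold, vlsm_template

__all__ = [
    "dice",
    "fwer_null_calibration",
    "planted_region_recovery",
    "sparseness_adaptivity",
    "size_location_dissociation",
    "residual_control_elimination",
    "factor_recovery",
]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two flat voxel index sets."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.size + b.size == 0:
        return 0.0
    return 2.0 * np.intersect1d(a, b).size / (a.size + b.size)


def fwer_null_calibration(
    seed: int,
    n_runs: int = 200,
    n: int = 60,
    grid: int = 20,
    B: int = 500,
    v: int = 100,
    alpha: float = 0.05,
) -> dict:
    """Empirical generalized-FWER rate under a pure-null score.

    One lesion cohort is simulated on a small grid; ``n_runs`` independent
    null score vectors are tested and the fraction of runs with at least
    v_eff surviving voxels is returned along with the binomial bound
    ``alpha + 2 * sqrt(alpha(1-alpha)/n_runs)``.
    """
    cfg = sim.ScenarioConfig(
        n_participants=n,
        grid=grid,
        territory_center=(6.25, 10.0, 10.0),
        territory_radii=(6.25, 7.5, 7.5),
        size_scale=0.02,
        seed=seed,
    )
    cohort, _ = sim.simulate_cohort(cfg)
    mask = build_analysis_mask(cohort)
    X = dtlvc_normalize(cohort, mask)
    rng = np.random.default_rng(seed + 1)
    rejections = 0
    v_eff = None
    for _ in range(n_runs):
        y = rng.normal(size=n)
        sm = continuous_fwer_threshold(X, y, B=B, v=v, alpha=alpha, rng=rng)
        v_eff = sm.params["v_eff"]
        rejections += int(sm.survivors.size >= v_eff)
    rate = rejections / n_runs
    bound = alpha + 2.0 * np.sqrt(alpha * (1 - alpha) / n_runs)
    return {"rate": rate, "bound": bound, "v_eff": v_eff, "n_runs": n_runs,
            "mask_voxels": mask.n_voxels}


def planted_region_recovery(
    seed: int, n_seeds: int = 20, n: int = 128, B: int = 300
) -> dict:
    """Dice overlap between LSM templates and the planted critical region.

    For each replicate cohort of the focal scenario, fits the full-sample
    VLSM template and the sparse template at the CV-optimized sparseness,
    and scores both against the ground-truth region.
    """
    dices_v, dices_s = [], []
    for i in range(n_seeds):
        cfg = sim.focal_scenario(seed=seed + i)
        cohort, truth = sim.simulate_cohort(cfg)
        mask = build_analysis_mask(cohort)
        region = truth.critical_regions["focal_deficit"]
        X = dtlvc_normalize(cohort, mask)
        y = cohort.behavior["focal_deficit"].to_numpy()
        sm = continuous_fwer_threshold(
            X, y, B=B, rng=np.random.default_rng(seed + 100 + i)
        )
        dices_v.append(dice(vlsm_template(sm).voxels, region))
        res = optimize_sparseness(
            X, y, rng=np.random.default_rng(seed + 200 + i)
        )
        tpl = sccan_template(sccan_fit(X, y, res.s_star))
        dices_s.append(dice(tpl.voxels, region))
    dices_v, dices_s = np.array(dices_v), np.array(dices_s)
    return {
        "vlsm_dice": dices_v,
        "sccan_dice": dices_s,
        "vlsm_hit_rate": float((dices_v >= 0.3).mean()),
        "sccan_hit_rate": float((dices_s >= 0.3).mean()),
    }


def sparseness_adaptivity(seed: int, n_pairs: int = 5, n: int = 128) -> dict:
    """Retained-voxel fractions for matched focal vs size-driven deficits.

    A focal deficit should end at a small optimized sparseness (few voxels
    retained); a purely size-driven deficit, whose association with the
    lesion map is diffuse, should end at a much larger one.
    """
    focal, diffuse = [], []
    for i in range(n_pairs):
        cfg = sim.ScenarioConfig(
            n_participants=n,
            deficit_models={
                "focal": sim.DeficitModel(
                    w_focal=1.0, critical_center=(12, 21, 16), noise_sd=1.0
                ),
                "size": sim.DeficitModel(w_size=1.0, noise_sd=1.0),
            },
            seed=seed + i,
        )
        cohort, _ = sim.simulate_cohort(cfg)
        mask = build_analysis_mask(cohort)
        X = dtlvc_normalize(cohort, mask)
        for name, acc in (("focal", focal), ("size", diffuse)):
            y = cohort.behavior[name].to_numpy()
            res = optimize_sparseness(
                X, y, rng=np.random.default_rng(seed + 300 + i)
            )
            acc.append(round(res.s_star * mask.n_voxels) / mask.n_voxels)
    return {
        "focal_fractions": focal,
        "size_fractions": diffuse,
        "focal_median": float(np.median(focal)),
        "size_median": float(np.median(diffuse)),
        "ratio": float(np.median(diffuse) / np.median(focal)),
    }


def size_location_dissociation(
    seed: int,
    n_replicates: int = 40,
    n: int = 128,
    B: int = 300,
    methods=("vlsm", "sccan"),
    alpha: float = 0.05,
) -> dict:
    """ΔR² significance rates for size-driven vs focal deficits.

    Runs the full 8-fold prediction pipeline on replicate cohorts of each
    scenario and counts, per method, how often adding template lesion load
    to a lesion-size model significantly improves R².  The expected pattern:
    rarely for size-driven deficits, almost always for focal ones.
    """
    out = {m: {"size": [], "focal": []} for m in methods}
    for i in range(n_replicates):
        cfg = sim.ScenarioConfig(
            n_participants=n,
            deficit_models={
                "focal": sim.DeficitModel(
                    w_focal=1.0, critical_center=(12, 21, 16), noise_sd=1.0
                ),
                "size": sim.DeficitModel(w_size=1.0, noise_sd=1.0),
            },
            seed=seed + 1000 + i,
        )
        cohort, _ = sim.simulate_cohort(cfg)
        deficits = {
            k: cohort.behavior[k].to_numpy() for k in ("focal", "size")
        }
        res = run_study2(
            cohort,
            deficits,
            seed=seed + 2000 + i,
            methods=methods,
            vlsm_params={"B": B, "v": 100, "alpha": 0.05},
        )
        for (name, method), mc in res.comparisons.items():
            out[method][name].append(mc.p_value < alpha)
    rates = {
        m: {k: float(np.mean(v)) for k, v in d.items()} for m, d in out.items()
    }
    return {"rates": rates, "n_replicates": n_replicates}


def residual_control_elimination(
    seed: int, n_runs: int = 20, n: int = 128, B: int = 300
) -> dict:
    """Behavior-side size control on size-driven deficits.

    After residualizing the score on lesion size, VLSM should find
    (almost) nothing: the fraction of runs with <= 1% surviving voxels is
    returned.
    """
    eliminated = []
    for i in range(n_runs):
        cfg = sim.size_driven_scenario(seed=seed + i)
        cohort, _ = sim.simulate_cohort(cfg)
        mask = build_analysis_mask(cohort)
        X = dtlvc_normalize(cohort, mask)
        y = cohort.behavior["size_deficit"].to_numpy()
        resid = behavior_residual_control(y, cohort.sizes_cc)
        sm = continuous_fwer_threshold(
            X, resid, B=B, rng=np.random.default_rng(seed + 400 + i)
        )
        eliminated.append(sm.survivors.size / mask.n_voxels <= 0.01)
    return {"elimination_rate": float(np.mean(eliminated)), "n_runs": n_runs}


def factor_recovery(seed: int, n: int = 128) -> dict:
    """Tucker congruence between recovered and planted battery loadings."""
    cfg = sim.battery_scenario(seed=seed, n=n)
    cohort, truth = sim.simulate_cohort(cfg)
    cols = [c for c in cohort.behavior.columns if c.startswith("measure")]
    model = fit_pca_varimax(cohort.behavior[cols], n_factors=3)
    aligned, _, _ = align_factors(model.loadings, truth.battery_loadings)
    cong = np.diag(tucker_congruence(aligned, truth.battery_loadings))
    return {
        "congruence": cong,
        "min_congruence": float(cong.min()),
        "eigenvalues": model.eigenvalues,
        "variance_explained": model.variance_explained,
    }
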