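"""Cross-validated lesion-load prediction: location beyond size.

The question: does lesion *location* predict a deficit beyond lesion
*size*?  The pipeline answers it without double-dipping:

1. participants are partitioned into k (default 8) balanced folds;
2. for each fold, an LSM analysis (mass-univariate VLSM or sparse
   multivariate mapping) is run on the training participants only and
   thresholded into a binary *template* of critical voxels;
3. each held-out participant's *template lesion load* — the fraction of the
   template falling inside their lesion — is computed from that
   independently trained template;
4. nested OLS models (size; load; size + load) are compared per deficit:
   the increment ΔR² = R²(size+load) − R²(size) is tested with the nested-
   model F test, and the partial correlation of load with the score
   controlling for size is reported.

A deficit that is really a lesion-size effect yields templates whose loads
add nothing over size (ΔR² ≈ 0); a focal deficit yields loads that carry
location information size cannot (significant ΔR²).

A more conservative behavior-side size control is also provided: residualize
the score on lesion size before mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    LesionCohort,
    LesionMask,
    Template,
    build_analysis_mask,
    dtlvc_normalize,
)
from . import sccan as _sccan
from . import vlsm as _vlsm

log = logging.getLogger(__name__)

__all__ = [
    "FoldAssignment",
    "ModelComparison",
    "Study2Result",
    "assign_folds",
    "template_lesion_load",
    "cross_validated_loads",
    "compare_models",
    "behavior_residual_control",
    "run_study2",
]


@dataclass(frozen=True)
class FoldAssignment:
    """Balanced random partition of participants into k folds (ids 1..k)."""

    fold_of: np.ndarray  # per-participant fold id, 1-based
    k: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


def assign_folds(
    n: int, k: int = 8, rng: np.random.Generator | None = None
) -> FoldAssignment:
    """Random balanced partition; fold sizes differ by at most one."""
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} participants")
    if k < 2:
        raise ValueError("need at least 2 folds")
    if rng is None:
        raise ValueError("rng required")
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for f, part in enumerate(np.array_split(perm, k), start=1):
        fold_of[part] = f
    return FoldAssignment(fold_of=fold_of, k=k)


def template_lesion_load(lesion: LesionMask, template: Template) -> float:
    """Fraction of the template's voxels inside the participant's lesion."""
    if template.size == 0:
        log.warning("empty template: lesion load undefined, returning 0")
        return 0.0
    flat = lesion.data.ravel()
    overlap = int(flat[template.voxels].sum())
    return overlap / template.size


def _fit_template(
    method: str,
    X,
    y: np.ndarray,
    method_params: dict,
    rng: np.random.Generator,
) -> Template:
    if method == "vlsm":
        sm = _vlsm.continuous_fwer_threshold(
            X,
            y,
            B=method_params.get("B", 300),
            v=method_params.get("v", 100),
            alpha=method_params.get("alpha", 0.05),
            rng=rng,
            direction=method_params.get("direction", "negative"),
        )
        return _vlsm.vlsm_template(sm)
    if method == "sccan":
        fit = _sccan.sccan_fit(X, y, s=method_params["s"])
        return _sccan.sccan_template(fit)
    raise ValueError(f"unknown LSM method {method!r}")


def cross_validated_loads(
    cohort: LesionCohort,
    scores: dict,
    method: str,
    folds: FoldAssignment,
    method_params: dict,
    min_frequency: float = 0.10,
    rebuild_mask: bool = True,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Held-out template lesion loads for every participant and deficit.

    For each fold, the analysis mask, dTLVC matrix and LSM template are
    derived from the *training* participants only; loads are then computed
    for the held-out participants, so no participant's lesion or score ever
    influences the template used for their own load.

    ``method_params``: for "vlsm", {B, v, alpha}; for "sccan", {"s": float}
    or {"s": {deficit_name: float}} (fixed sparseness per deficit).

    Returns (table, template_sizes) where the table has one row per
    participant (lesion_size_cc plus one ``load_<deficit>`` column) and
    template_sizes maps deficit -> per-fold template voxel counts.
    """
    n = len(cohort)
    if folds.fold_of.shape[0] != n:
        raise ValueError("fold assignment does not match cohort size")
    table = pd.DataFrame(
        {
            "participant_id": cohort.participant_ids,
            "lesion_size_cc": cohort.sizes_cc,
        }
    )
    for name in scores:
        table[f"load_{name}"] = np.nan
    template_sizes: dict = {name: [] for name in scores}

    full_mask = None
    if not rebuild_mask:
        full_mask = build_analysis_mask(cohort, min_frequency)

    ss = np.random.SeedSequence(seed)
    fold_seeds = ss.spawn(folds.k)
    for f in range(1, folds.k + 1):
        train_idx = folds.train_indices(f)
        test_idx = folds.test_indices(f)
        train = cohort.subset(train_idx)
        mask = full_mask if full_mask is not None else build_analysis_mask(
            train, min_frequency
        )
        X = dtlvc_normalize(train, mask)
        rng = np.random.Generator(np.random.PCG64(fold_seeds[f - 1]))
        for name, y in scores.items():
            params = dict(method_params)
            if method == "sccan" and isinstance(params.get("s"), dict):
                params["s"] = params["s"][name]
            tpl = _fit_template(method, X, np.asarray(y)[train_idx], params, rng)
            template_sizes[name].append(tpl.size)
            if tpl.size == 0:
                log.warning(
                    "fold %d, deficit %s: empty training template; "
                    "held-out loads set to 0",
                    f,
                    name,
                )
            col = table.columns.get_loc(f"load_{name}")
            for i in test_idx:
                table.iloc[i, col] = (
                    template_lesion_load(cohort.masks[i], tpl)
                    if tpl.size
                    else 0.0
                )
    return table, template_sizes


@dataclass
class ModelComparison:
    """Nested OLS comparison of size-only, load-only and size+load models."""

    r2_size: float
    r2_load: float
    r2_both: float
    delta_r2: float
    f_stat: float
    p_value: float
    partial_r: float
    n: int

    def as_dict(self) -> dict:
        return {
            "r2_size": self.r2_size,
            "r2_load": self.r2_load,
            "r2_both": self.r2_both,
            "delta_r2": self.delta_r2,
            "f_stat": self.f_stat,
            "p_value": self.p_value,
            "partial_r": self.partial_r,
            "n": self.n,
        }


def _ols_r2(y: np.ndarray, predictors: list[np.ndarray]) -> float:
    """R² of OLS with intercept; constant predictors contribute nothing."""
    n = y.shape[0]
    cols = [np.ones(n)]
    for x in predictors:
        if np.std(x) > 0:
            cols.append((x - x.mean()) / x.std())
        else:
            log.warning("constant predictor dropped from model (R² = 0 alone)")
    D = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        return 0.0
    return float(max(0.0, 1.0 - (resid**2).sum() / tss))


def _residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    D = np.column_stack([np.ones_like(x, dtype=float), x])
    beta, *_ = np.linalg.lstsq(D, np.asarray(y, dtype=float), rcond=None)
    return y - D @ beta


def compare_models(
    score: np.ndarray, size_cc: np.ndarray, load: np.ndarray
) -> ModelComparison:
    """Hierarchical model comparison for one deficit.

    Fits score ~ size, score ~ load, and score ~ size + load by OLS
    (predictors z-scored, intercepts included), tests ΔR² with the nested F
    test on (1, n-3) df, and computes the partial correlation of load with
    the score controlling for size via residual-residual correlation.
    """
    score = np.asarray(score, dtype=float)
    size_cc = np.asarray(size_cc, dtype=float)
    load = np.asarray(load, dtype=float)
    n = score.shape[0]
    if not (size_cc.shape[0] == load.shape[0] == n):
        raise ValueError("score, size and load must be aligned")
    if n < 4:
        raise ValueError("need at least 4 participants")

    r2_size = _ols_r2(score, [size_cc])
    r2_load = _ols_r2(score, [load])
    r2_both = _ols_r2(score, [size_cc, load])
    delta = max(0.0, r2_both - r2_size)
    df2 = n - 3
    if r2_both >= 1.0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = delta / ((1.0 - r2_both) / df2)
        p = float(stats.f.sf(f_stat, 1, df2))

    rs = _residuals(score, size_cc)
    rl = _residuals(load, size_cc)
    # residuals that are pure numerical noise mean the predictor carries no
    # information beyond size: partial correlation is 0 by definition
    tol_s = 1e-10 * max(1.0, float(np.std(score)))
    tol_l = 1e-10 * max(1.0, float(np.std(load)))
    if np.std(rs) <= tol_s or np.std(rl) <= tol_l:
        partial_r = 0.0
    else:
        partial_r = float(np.corrcoef(rs, rl)[0, 1])
    return ModelComparison(
        r2_size=r2_size,
        r2_load=r2_load,
        r2_both=r2_both,
        delta_r2=delta,
        f_stat=float(f_stat),
        p_value=p,
        partial_r=partial_r,
        n=n,
    )


def behavior_residual_control(
    score: np.ndarray, size_cc: np.ndarray
) -> np.ndarray:
    """Residual deficit scores after regressing out lesion size.

    A conservative behavior-side size control: the residuals are zero-mean
    and exactly uncorrelated with lesion size.
    """
    score = np.asarray(score, dtype=float)
    size_cc = np.asarray(size_cc, dtype=float)
    return _residuals(score, size_cc)


@dataclass
class Study2Result:
    """Per-deficit, per-method model comparisons plus supporting artifacts."""

    comparisons: dict  # (deficit, method) -> ModelComparison
    predictors: dict  # method -> DataFrame
    template_sizes: dict  # method -> {deficit: [per-fold sizes]}
    sparseness: dict  # deficit -> selected s (sccan)
    folds: FoldAssignment
    seed: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for (name, method), mc in self.comparisons.items():
            rows.append(
                {
                    "deficit": name,
                    "method": method,
                    **mc.as_dict(),
                    "significant": mc.p_value < 0.05,
                }
            )
        return pd.DataFrame(rows)


def run_study2(
    cohort: LesionCohort,
    deficits: dict,
    seed: int,
    methods=("vlsm", "sccan"),
    k_folds: int = 8,
    vlsm_params: dict | None = None,
    sccan_grid=_sccan.DEFAULT_GRID,
    sccan_tolerance: float = 0.02,
    min_frequency: float = 0.10,
    rebuild_mask: bool = True,
) -> Study2Result:
    """Full prediction pipeline for a set of named deficit scores.

    For the sparse method, per-deficit sparseness is first optimized on the
    full sample (4-fold CV) and then held fixed across the outer prediction
    folds, keeping templates comparable across folds.
    """
    vlsm_params = dict(vlsm_params or {"B": 300, "v": 100, "alpha": 0.05})
    root = np.random.SeedSequence(seed)
    fold_rng = np.random.Generator(np.random.PCG64(root.spawn(1)[0]))
    folds = assign_folds(len(cohort), k_folds, fold_rng)

    sparseness: dict = {}
    if "sccan" in methods:
        mask = build_analysis_mask(cohort, min_frequency)
        X_full = dtlvc_normalize(cohort, mask)
        s_rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(11,)))
        )
        for name, y in deficits.items():
            res = _sccan.optimize_sparseness(
                X_full,
                np.asarray(y),
                grid=sccan_grid,
                tolerance=sccan_tolerance,
                rng=s_rng,
            )
            sparseness[name] = res.s_star

    comparisons: dict = {}
    predictors: dict = {}
    tpl_sizes: dict = {}
    for m_i, method in enumerate(methods):
        params = (
            {"s": sparseness} if method == "sccan" else vlsm_params
        )
        table, sizes = cross_validated_loads(
            cohort,
            deficits,
            method,
            folds,
            params,
            min_frequency=min_frequency,
            rebuild_mask=rebuild_mask,
            seed=int(root.entropy % (2**31)) + 101 * m_i,
        )
        predictors[method] = table
        tpl_sizes[method] = sizes
        for name, y in deficits.items():
            comparisons[(name, method)] = compare_models(
                np.asarray(y),
                cohort.sizes_cc,
                table[f"load_{name}"].to_numpy(),
            )
    return Study2Result(
        comparisons=comparisons,
        predictors=predictors,
        template_sizes=tpl_sizes,
        sparseness=sparseness,
        folds=folds,
        seed=seed,
    )
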