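"""Synthetic stroke-lesion cohorts with known ground truth.

Real lesion-symptom datasets are rarely shareable, so every stage of the
pipeline is exercised against simulated cohorts that reproduce the
statistical structure the analyses assume:

* lesions concentrated in one vascular territory (an ellipsoidal probability
  field standing in for the middle-cerebral-artery territory), grown by
  stochastic 26-connected region growing so that larger lesions naturally
  cover more of any critical region — the size/location confound the
  downstream analyses are designed to tease apart;
* lesion sizes drawn from a truncated lognormal whose shape matches the
  heavy-tailed size distributions of chronic left-hemisphere stroke samples
  (mean ~101 cc, SD ~83 cc, range ~5-376 cc), linearly rescaled to fit the
  desk-scale grid;
* deficit scores driven by lesion size, by damage to a planted critical
  region, or both, plus Gaussian noise;
* multi-measure test batteries with a planted factor structure for the
  factor-analysis stage.

Every simulated cohort carries a :class:`GroundTruth` sufficient to
recompute its noiseless scores, enabling recovery testing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cohort import LesionCohort, LesionMask, VolumeGeometry

__all__ = [
    "DeficitModel",
    "BatterySpec",
    "ScenarioConfig",
    "GroundTruth",
    "desk_geometry",
    "critical_ball",
    "make_territory",
    "simulate_lesion",
    "simulate_cohort",
    "generate_deficits",
    "generate_battery",
    "focal_scenario",
    "size_driven_scenario",
    "null_scenario",
    "battery_scenario",
]

# lognormal fit to a chronic left-hemisphere stroke sample:
# mean 100.97 cc, SD 82.76 cc  ->  sigma^2 = ln(1 + (SD/mean)^2)
_SIZE_MEAN_LOG = 4.358
_SIZE_SD_LOG = 0.717
_SIZE_MIN_CC = 5.38
_SIZE_MAX_CC = 376.12


def desk_geometry(n: int = 32, voxel_mm: float = 2.0) -> VolumeGeometry:
    """Default desk-scale grid: 32x32x32 at 2 mm isotropic."""
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    return VolumeGeometry(shape=(n, n, n), affine=aff)


def critical_ball(
    geometry: VolumeGeometry, center, radius: float
) -> np.ndarray:
    """Flat indices of a voxel ball; the usual shape for planted regions."""
    grid = np.indices(geometry.shape).reshape(3, -1).T
    d2 = ((grid - np.asarray(center, dtype=float)) ** 2).sum(axis=1)
    idx = np.flatnonzero(d2 <= radius**2)
    if idx.size == 0:
        raise ValueError("critical ball contains no voxels")
    return idx


@dataclass
class DeficitModel:
    """Generative model for one deficit score.

    score_i = - w_size * z(lesion size_i) - w_focal * z(critical load_i)
              + Normal(0, noise_sd)

    where critical load is the damaged fraction of the critical region and
    z() is the cohort z-score of the driver.  With a single unit-weight
    driver and noise_sd = 1 the generative R^2 is 0.5.
    """

    w_size: float = 0.0
    w_focal: float = 0.0
    critical_center: tuple | None = None
    critical_radius: float = 2.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.w_size < 0 or self.w_focal < 0 or self.noise_sd < 0:
            raise ValueError("weights and noise_sd must be non-negative")
        if self.w_focal > 0 and self.critical_center is None:
            raise ValueError("focal deficit requires a critical region")


@dataclass
class BatterySpec:
    """Planted-factor battery: measures = F . loadings^T + uniqueness noise.

    Latent factors are built from per-factor critical-region damage loads
    (each factor has its own planted ball), z-scored and, by default,
    symmetrically whitened (ZCA) so the planted factors are orthogonal while
    each stays maximally tied to its own region's damage.
    """

    loadings: np.ndarray  # measures x factors
    factor_centers: list
    factor_radius: float = 2.0
    uniqueness_sd: float | np.ndarray = 0.6
    whiten_latents: bool = True

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        if not np.isfinite(self.loadings).all():
            raise ValueError("loadings must be finite")
        if len(self.factor_centers) != self.loadings.shape[1]:
            raise ValueError("one planted region per factor required")

    @property
    def n_measures(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]


@dataclass
class ScenarioConfig:
    """Full recipe for one simulated cohort; reproducible from seed alone."""

    n_participants: int = 128
    grid: int = 32
    voxel_mm: float = 2.0
    territory_center: tuple = (10.0, 16.0, 16.0)
    territory_radii: tuple = (10.0, 12.0, 12.0)
    size_mean_log: float = _SIZE_MEAN_LOG
    size_sd_log: float = _SIZE_SD_LOG
    size_min_cc: float = _SIZE_MIN_CC
    size_max_cc: float = _SIZE_MAX_CC
    size_scale: float = 0.03  # linear cc -> desk-scale cc factor
    deficit_models: dict = field(default_factory=dict)
    battery: BatterySpec | None = None
    seed: int = 0

    @property
    def geometry(self) -> VolumeGeometry:
        return desk_geometry(self.grid, self.voxel_mm)

    # --- YAML round trip -------------------------------------------------
    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        if d["battery"] is not None:
            d["battery"]["loadings"] = self.battery.loadings.tolist()
            u = d["battery"]["uniqueness_sd"]
            if isinstance(u, np.ndarray):
                d["battery"]["uniqueness_sd"] = u.tolist()
        for key in ("territory_center", "territory_radii"):
            d[key] = list(d[key])
        for m in d["deficit_models"].values():
            if m["critical_center"] is not None:
                m["critical_center"] = list(m["critical_center"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("battery") is not None:
            d["battery"] = BatterySpec(**d["battery"])
        d["deficit_models"] = {
            k: DeficitModel(**v) for k, v in d.get("deficit_models", {}).items()
        }
        for key in ("territory_center", "territory_radii"):
            d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Everything needed to recompute a cohort's noiseless scores."""

    critical_regions: dict  # deficit/factor name -> flat voxel indices
    critical_loads: dict  # name -> per-participant damaged fraction
    latent_factors: np.ndarray | None  # participants x factors
    battery_loadings: np.ndarray | None
    weights: dict  # name -> (w_size, w_focal, noise_sd)

    def save(self, path) -> None:
        d = {
            "critical_regions": {
                k: np.asarray(v).tolist() for k, v in self.critical_regions.items()
            },
            "critical_loads": {
                k: np.asarray(v).tolist() for k, v in self.critical_loads.items()
            },
            "latent_factors": None
            if self.latent_factors is None
            else self.latent_factors.tolist(),
            "battery_loadings": None
            if self.battery_loadings is None
            else self.battery_loadings.tolist(),
            "weights": self.weights,
        }
        with open(path, "w") as fh:
            json.dump(d, fh)


# ---------------------------------------------------------------------------
# territory + lesion growth


def make_territory(
    geometry: VolumeGeometry, center, radii, floor: float = 0.011
) -> np.ndarray:
    """Ellipsoidal Gaussian probability field with hard compact support.

    ``p = exp(-4.5 * d^2)`` inside the ellipsoid ``d <= 1`` (where *d* is
    the normalized ellipsoidal distance) and exactly 0 outside, so the
    support is a single connected region and probabilities lie in
    (floor, 1].
    """
    center = np.asarray(center, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if (radii <= 0).any():
        raise ValueError("territory radii must be positive (empty support)")
    grid = np.indices(geometry.shape).astype(float)
    d2 = sum(
        ((grid[a] - center[a]) / radii[a]) ** 2 for a in range(3)
    )
    terr = np.where(d2 <= 1.0, np.exp(-4.5 * d2), 0.0)
    if not (terr > 0).any():
        raise ValueError("territory has empty support")
    return terr


_NEIGHBOR_OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
)


def _neighbors_flat(flat_idx: np.ndarray, shape) -> np.ndarray:
    """26-neighborhood of flat indices, boundary-clipped, possibly repeated."""
    coords = np.array(np.unravel_index(flat_idx, shape)).T  # k x 3
    nb = coords[:, None, :] + _NEIGHBOR_OFFSETS[None, :, :]  # k x 26 x 3
    nb = nb.reshape(-1, 3)
    ok = ((nb >= 0) & (nb < np.asarray(shape))).all(axis=1)
    nb = nb[ok]
    return np.ravel_multi_index(nb.T, shape)


def simulate_lesion(
    territory: np.ndarray,
    target_size: int,
    rng: np.random.Generator,
    step_fraction: float = 0.25,
) -> np.ndarray:
    """Grow one 26-connected lesion of exactly ``target_size`` voxels.

    The seed voxel is sampled proportionally to the territory probability;
    growth then repeatedly samples a chunk of the current frontier (again
    proportionally to territory probability) until the target is reached.
    Chunked sampling keeps growth fast at desk scale without changing the
    qualitative morphology.

    Returns the boolean lesion volume.  Raises if the connected support is
    exhausted before the target size is reached.
    """
    shape = territory.shape
    probs = territory.ravel()
    support = np.flatnonzero(probs > 0)
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    if target_size > support.size:
        raise ValueError(
            f"target size {target_size} exceeds territory support {support.size}"
        )
    in_lesion = np.zeros(probs.size, dtype=bool)
    in_frontier = np.zeros(probs.size, dtype=bool)

    p0 = probs[support]
    seed = support[rng.choice(support.size, p=p0 / p0.sum())]
    in_lesion[seed] = True
    count = 1

    nb = np.unique(_neighbors_flat(np.array([seed]), shape))
    nb = nb[(probs[nb] > 0) & ~in_lesion[nb]]
    frontier = nb
    in_frontier[nb] = True

    while count < target_size:
        if frontier.size == 0:
            raise RuntimeError(
                "territory support exhausted before reaching target size"
            )
        remaining = target_size - count
        chunk = min(remaining, max(1, int(frontier.size * step_fraction)))
        w = probs[frontier]
        pick = rng.choice(
            frontier.size, size=chunk, replace=False, p=w / w.sum()
        )
        chosen = frontier[pick]
        in_lesion[chosen] = True
        in_frontier[chosen] = False
        count += chunk

        keep = frontier[~in_lesion[frontier]]
        new = np.unique(_neighbors_flat(chosen, shape))
        new = new[(probs[new] > 0) & ~in_lesion[new] & ~in_frontier[new]]
        in_frontier[new] = True
        frontier = np.concatenate([keep, new])
    return in_lesion.reshape(shape)


# ---------------------------------------------------------------------------
# scores


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _region_loads(cohort: LesionCohort, region_idx: np.ndarray) -> np.ndarray:
    """Damaged fraction of a voxel region, per participant."""
    loads = np.empty(len(cohort))
    for i, m in enumerate(cohort.masks):
        flat = m.data.ravel()
        loads[i] = flat[region_idx].sum() / region_idx.size
    return loads


def generate_deficits(
    cohort: LesionCohort,
    model: DeficitModel,
    rng: np.random.Generator,
    critical_region: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Draw one deficit score vector; returns (scores, critical loads)."""
    score = np.zeros(len(cohort))
    loads = None
    if model.w_size > 0:
        score -= model.w_size * _zscore(cohort.sizes_voxels())
    if model.w_focal > 0:
        if critical_region is None:
            critical_region = critical_ball(
                cohort.geometry, model.critical_center, model.critical_radius
            )
        loads = _region_loads(cohort, critical_region)
        score -= model.w_focal * _zscore(loads)
    elif critical_region is not None:
        loads = _region_loads(cohort, critical_region)
    if model.noise_sd > 0:
        score += rng.normal(0.0, model.noise_sd, size=len(cohort))
    return score, loads


def generate_battery(
    cohort: LesionCohort,
    spec: BatterySpec,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Planted-factor battery table; returns (table, latents, factor regions)."""
    regions = {
        f"factor_{f + 1}": critical_ball(
            cohort.geometry, c, spec.factor_radius
        )
        for f, c in enumerate(spec.factor_centers)
    }
    raw = np.column_stack(
        [_zscore(_region_loads(cohort, r)) for r in regions.values()]
    )
    if spec.whiten_latents and raw.shape[0] > raw.shape[1]:
        cov = np.cov(raw.T)
        vals, vecs = np.linalg.eigh(cov)
        vals = np.clip(vals, 1e-10, None)
        zca = vecs @ np.diag(vals**-0.5) @ vecs.T  # symmetric whitening
        latents = raw @ zca
    else:
        latents = raw
    noise = rng.normal(size=(len(cohort), spec.n_measures))
    u = np.broadcast_to(
        np.asarray(spec.uniqueness_sd, dtype=float), (spec.n_measures,)
    )
    table = latents @ spec.loadings.T + noise * u
    cols = [f"measure_{j + 1:02d}" for j in range(spec.n_measures)]
    return pd.DataFrame(table, columns=cols), latents, regions


# ---------------------------------------------------------------------------
# cohort assembly


def simulate_cohort(config: ScenarioConfig) -> tuple[LesionCohort, GroundTruth]:
    """Simulate a full cohort from a scenario config, reproducibly.

    All randomness descends from ``config.seed`` through a splittable
    SeedSequence; each participant's lesion has its own child stream indexed
    by position, so cohorts are bit-identical across reruns.
    """
    n = config.n_participants
    if n < 1:
        raise ValueError("n_participants must be >= 1")
    geometry = config.geometry
    territory = make_territory(
        geometry, config.territory_center, config.territory_radii
    )
    support_size = int((territory > 0).sum())

    ss = np.random.SeedSequence(config.seed)
    size_rng = np.random.Generator(np.random.PCG64(ss.spawn(1)[0]))
    lesion_seeds = np.random.SeedSequence(config.seed, spawn_key=(1,)).spawn(n)
    score_rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(config.seed, spawn_key=(2,)))
    )

    # truncated lognormal sizes in cc, linearly rescaled to the grid
    voxel_cc = geometry.voxel_volume_mm3 / 1000.0
    sizes_vox = np.empty(n, dtype=int)
    for i in range(n):
        while True:
            cc = size_rng.lognormal(config.size_mean_log, config.size_sd_log)
            if config.size_min_cc <= cc <= config.size_max_cc:
                break
        vox = int(round(cc * config.size_scale / voxel_cc))
        sizes_vox[i] = min(max(vox, 1), support_size)

    masks = []
    for i in range(n):
        rng_i = np.random.Generator(np.random.PCG64(lesion_seeds[i]))
        data = simulate_lesion(territory, int(sizes_vox[i]), rng_i)
        masks.append(LesionMask(participant_id=f"sub-{i + 1:03d}", data=data))

    behavior = pd.DataFrame(index=range(n))
    cohort = LesionCohort(geometry=geometry, masks=masks, behavior=behavior)

    regions: dict = {}
    loads: dict = {}
    weights: dict = {}
    for name, model in config.deficit_models.items():
        region = None
        if model.critical_center is not None:
            region = critical_ball(
                geometry, model.critical_center, model.critical_radius
            )
            regions[name] = region
        score, load = generate_deficits(
            cohort, model, score_rng, critical_region=region
        )
        behavior[name] = score
        if load is not None:
            loads[name] = load
        weights[name] = {
            "w_size": model.w_size,
            "w_focal": model.w_focal,
            "noise_sd": model.noise_sd,
        }

    latents = None
    loadings = None
    if config.battery is not None:
        table, latents, factor_regions = generate_battery(
            cohort, config.battery, score_rng
        )
        for col in table.columns:
            behavior[col] = table[col].to_numpy()
        regions.update(factor_regions)
        for fname, r in factor_regions.items():
            loads[fname] = _region_loads(cohort, r)
        loadings = config.battery.loadings

    cohort.behavior = behavior
    truth = GroundTruth(
        critical_regions=regions,
        critical_loads=loads,
        latent_factors=latents,
        battery_loadings=loadings,
        weights=weights,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# canned scenarios

_FOCAL_CENTER = (12.0, 21.0, 16.0)


def focal_scenario(
    seed: int,
    n: int = 128,
    w_focal: float = 1.0,
    noise_sd: float = 1.0,
    name: str = "focal_deficit",
) -> ScenarioConfig:
    """Deficit driven by damage to a small critical region (~1% of mask)."""
    return ScenarioConfig(
        n_participants=n,
        deficit_models={
            name: DeficitModel(
                w_focal=w_focal,
                critical_center=_FOCAL_CENTER,
                critical_radius=2.0,
                noise_sd=noise_sd,
            )
        },
        seed=seed,
    )


def size_driven_scenario(
    seed: int,
    n: int = 128,
    w_size: float = 1.0,
    noise_sd: float = 1.0,
    name: str = "size_deficit",
) -> ScenarioConfig:
    """Deficit driven by overall lesion size only (diffuse association)."""
    return ScenarioConfig(
        n_participants=n,
        deficit_models={name: DeficitModel(w_size=w_size, noise_sd=noise_sd)},
        seed=seed,
    )


def null_scenario(seed: int, n: int = 128, name: str = "null_deficit") -> ScenarioConfig:
    """Pure-noise deficit unrelated to the lesions."""
    return ScenarioConfig(
        n_participants=n,
        deficit_models={name: DeficitModel(noise_sd=1.0)},
        seed=seed,
    )


def battery_scenario(
    seed: int, n: int = 128, uniqueness_sd: float = 0.6
) -> ScenarioConfig:
    """17-measure battery with 3 planted factors (6+6+5 simple structure)."""
    loadings = np.zeros((17, 3))
    loadings[0:6, 0] = 0.8
    loadings[6:12, 1] = 0.8
    loadings[12:17, 2] = 0.8
    spec = BatterySpec(
        loadings=loadings,
        factor_centers=[(8.0, 12.0, 12.0), (11.0, 19.0, 16.0), (9.0, 16.0, 21.0)],
        factor_radius=2.0,
        uniqueness_sd=uniqueness_sd,
    )
    return ScenarioConfig(n_participants=n, battery=spec, seed=seed)
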