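"""Mass-univariate voxel-based lesion-symptom mapping (VLSM).

Each in-mask voxel is tested independently for association between damage
(the dTLVC-scaled lesion value) and a behavioral score, via the t statistic
of the simple-regression slope (equivalently the Pearson-r t transform).
Multiple comparisons are handled by permutation-based *continuous*
(generalized) family-wise error control of order ``v``: for each of B
permutations of the score vector the v-th most extreme voxel statistic in
the deficit direction is recorded, and the critical value is the (1-alpha)
nearest-rank quantile of that null distribution.  This bounds the
probability of ``v`` or more false-positive voxels at ``alpha``; ``v = 1``
reduces to classical max-statistic FWER.

``v`` is conventionally quoted for whole-brain masks of ~1.5e5 voxels; on
smaller grids it is rescaled proportionally (``scale_v``) so the nominal
order keeps the same meaning as a fraction of the mask.

Deficit scores are coded higher = better, so the default test is one-sided
toward damage predicting *lower* scores (negative t).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .cohort import AnalysisMask, NormalizedLesionMatrix, Template

log = logging.getLogger(__name__)

__all__ = [
    "StatMap",
    "voxelwise_statistic",
    "continuous_fwer_threshold",
    "vlsm_template",
]

_T_CAP = 1e6  # stand-in for +/- infinity at |r| = 1


def _design(X) -> tuple[np.ndarray, AnalysisMask | None]:
    if isinstance(X, NormalizedLesionMatrix):
        return X.values, X.source_mask
    return np.asarray(X, dtype=float), None


def _t_from_r(r: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * math.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    return np.nan_to_num(t, posinf=_T_CAP, neginf=-_T_CAP)


def _t_matrix(Xc: np.ndarray, xc_norm: np.ndarray, Yc: np.ndarray) -> np.ndarray:
    """t statistics for every (voxel, score-column) pair.

    ``Xc`` is the column-centered design (n x p) with column norms
    ``xc_norm``; ``Yc`` is one or more centered score vectors (n x B).
    Zero-variance voxels get t = 0.
    """
    n = Xc.shape[0]
    y_norm = np.linalg.norm(Yc, axis=0)
    y_norm = np.where(y_norm > 0, y_norm, np.inf)
    # columns whose norm is numerical noise are zero-variance voxels
    tol = 1e-12 * max(1.0, float(xc_norm.max(initial=0.0)))
    safe_x = np.where(xc_norm > tol, xc_norm, np.inf)
    r = (Xc.T @ Yc) / np.outer(safe_x, y_norm)
    return _t_from_r(r, n)


def voxelwise_statistic(X, y: np.ndarray) -> np.ndarray:
    """Per-voxel t statistic of the regression of ``y`` on each voxel.

    Negative values mean damage predicts lower scores.  Voxels with zero
    variance across participants (e.g. damaged in everyone) cannot carry a
    statistic and are set to 0 with a warning; |r| = 1 voxels are capped at
    +/-1e6 and flagged.
    """
    Xv, _ = _design(X)
    y = np.asarray(y, dtype=float)
    if Xv.shape[0] != y.shape[0]:
        raise ValueError("X rows and y length differ")
    Xc = Xv - Xv.mean(axis=0)
    xc_norm = np.linalg.norm(Xc, axis=0)
    tol = 1e-12 * max(1.0, float(xc_norm.max(initial=0.0)))
    n_dropped = int((xc_norm <= tol).sum())
    if n_dropped:
        log.warning("%d zero-variance voxel(s) excluded (t set to 0)", n_dropped)
    t = _t_matrix(Xc, xc_norm, (y - y.mean())[:, None])[:, 0]
    if (np.abs(t) >= _T_CAP).any():
        log.warning("perfectly collinear voxel(s): t capped at +/-%g", _T_CAP)
    return t


@dataclass
class StatMap:
    """Voxelwise statistics with a permutation-derived critical value.

    ``threshold`` lives on the extremeness scale (e.g. ``-t`` for the
    default damage->deficit direction); ``survivors`` are flat voxel
    indices into the analysis geometry.
    """

    statistic: np.ndarray
    threshold: float
    survivors: np.ndarray
    survivor_cols: np.ndarray
    mask: AnalysisMask
    params: dict = field(default_factory=dict)
    null_extremes: np.ndarray | None = None


def _extremeness(t: np.ndarray, direction: str) -> np.ndarray:
    if direction == "negative":
        return -t
    if direction == "positive":
        return t
    if direction == "two_sided":
        return np.abs(t)
    raise ValueError(f"unknown direction {direction!r}")


def effective_order(v: int, n_voxels: int, reference_voxels: int = 150_000) -> int:
    """Rescale the FWER order v to the current mask size.

    ``v`` is interpreted as an order for a reference whole-brain mask
    (~1.5e5 voxels); on a mask of ``n_voxels`` the effective order is
    ``max(1, round(v * n_voxels / reference_voxels))``.
    """
    return max(1, round(v * n_voxels / reference_voxels))


def continuous_fwer_threshold(
    X,
    y: np.ndarray,
    B: int = 1000,
    v: int = 100,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    direction: str = "negative",
    scale_v: bool = True,
    v_reference_voxels: int = 150_000,
    permutations: np.ndarray | None = None,
) -> StatMap:
    """Generalized (order-v) FWER threshold by score permutation.

    For each permutation of ``y`` the v-th most extreme voxel t (in the
    deficit direction) is recorded; the critical value is the (1-alpha)
    nearest-rank quantile of these B null values.  Observed voxels at or
    beyond the critical value (ties included) survive.

    ``permutations`` may supply an explicit (B x n) index array (e.g. the
    full enumeration for small n), overriding the Monte-Carlo draw.
    """
    Xv, mask = _design(X)
    y = np.asarray(y, dtype=float)
    n, p = Xv.shape
    v_eff = effective_order(v, p, v_reference_voxels) if scale_v else int(v)
    if v_eff > p:
        raise ValueError(f"order v={v_eff} exceeds {p} in-mask voxels")
    if permutations is None:
        if B < 100:
            raise ValueError("need at least 100 permutations")
        if rng is None:
            raise ValueError("rng required for Monte-Carlo permutations")
        permutations = np.stack([rng.permutation(n) for _ in range(B)])
    else:
        permutations = np.asarray(permutations)
        B = permutations.shape[0]

    Xc = Xv - Xv.mean(axis=0)
    xc_norm = np.linalg.norm(Xc, axis=0)
    yc = y - y.mean()
    if np.all(yc == 0):
        log.warning("score vector is constant: no voxel can be associated")
        return StatMap(
            statistic=np.zeros(p),
            threshold=np.inf,
            survivors=np.array([], dtype=np.int64),
            survivor_cols=np.array([], dtype=np.int64),
            mask=mask,
            params={"B": int(B), "v": int(v), "v_eff": int(v_eff),
                    "alpha": float(alpha), "direction": direction,
                    "scale_v": bool(scale_v)},
        )

    t_obs = _t_matrix(Xc, xc_norm, yc[:, None])[:, 0]
    e_obs = _extremeness(t_obs, direction)

    # all permuted score vectors at once: p x B statistic matrix
    Yp = yc[permutations.T]  # n x B
    t_null = _t_matrix(Xc, xc_norm, Yp)
    e_null = _extremeness(t_null, direction)
    # v-th most extreme voxel per permutation
    m = np.partition(e_null, p - v_eff, axis=0)[p - v_eff, :]

    k = math.ceil((1.0 - alpha) * B)  # nearest-rank quantile
    threshold = float(np.sort(m)[k - 1])
    cols = np.flatnonzero(e_obs >= threshold)
    voxels = mask.voxel_index[cols] if mask is not None else cols
    return StatMap(
        statistic=t_obs,
        threshold=threshold,
        survivors=voxels,
        survivor_cols=cols,
        mask=mask,
        params={
            "B": int(B),
            "v": int(v),
            "v_eff": int(v_eff),
            "alpha": float(alpha),
            "direction": direction,
            "scale_v": bool(scale_v),
        },
        null_extremes=np.sort(m),
    )


def vlsm_template(statmap: StatMap, provenance: str = "vlsm") -> Template:
    """Binary critical-region template from a thresholded stat map."""
    if statmap.survivors.size == 0:
        log.info("VLSM template is empty (no voxels survived correction)")
    if statmap.mask is None:
        raise ValueError("stat map carries no analysis mask geometry")
    return Template(
        geometry=statmap.mask.geometry,
        voxels=statmap.survivors,
        provenance=provenance,
    )
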