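"""Sparse multivariate lesion-symptom mapping.

A single sparse voxel-weight vector ``w`` is estimated so that the
projection of the dTLVC lesion matrix, ``X w``, correlates maximally with
the deficit score, subject to a sparseness constraint: at most
``round(s * p)`` voxels carry nonzero weight, where ``s`` in (0, 1] is the
sparseness parameter (larger s = less sparse, more voxels retained).

The solver is a truncated-projection iteration: the weight vector is
initialized from the score gradient ``X^T y``, hard-thresholded to the
``round(s p)`` largest-magnitude entries, and then refined by alternating
(a) least-squares projection of the score onto the current support's column
span and (b) re-ranking voxels by the gradient against that projection,
until the support is stable.  There is no internal randomness.

Sparseness itself is selected by k-fold cross-validation: the quality of a
solution is the Pearson correlation between pooled held-out projections and
the observed scores (the *CV correlation*), and the search prefers the
sparsest value whose CV correlation is within a small tolerance of the best
— a bias toward sparser solutions.  Focal lesion-deficit associations thus
end at small s, while diffuse, size-like associations end at large s, in
which case the retained region approaches the whole lesion territory and
the projection is effectively a lesion-size proxy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cohort import AnalysisMask, NormalizedLesionMatrix, Template
from .vlsm import _design

log = logging.getLogger(__name__)

__all__ = [
    "SparseWeightMap",
    "SparsenessSearchResult",
    "sccan_fit",
    "cv_correlation",
    "optimize_sparseness",
    "sccan_template",
    "DEFAULT_GRID",
]

DEFAULT_GRID = (0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass
class SparseWeightMap:
    """Unit-norm sparse voxel weights with their support.

    Weights live on the solver's internally standardized voxel scale;
    ``column_means``/``column_sds`` record the standardization so new
    participants can be projected consistently.
    """

    weights: np.ndarray
    sparseness: float
    support: np.ndarray  # column indices into the analysis mask
    mask: AnalysisMask | None = None
    column_means: np.ndarray | None = None
    column_sds: np.ndarray | None = None
    n_iter: int = 0

    @property
    def support_size(self) -> int:
        return int(self.support.size)

    def project(self, Xnew: np.ndarray) -> np.ndarray:
        """Project new rows (same in-mask columns) onto the weight vector."""
        return ((np.asarray(Xnew, dtype=float) - self.column_means)
                / self.column_sds) @ self.weights


@dataclass
class SparsenessSearchResult:
    """Outcome of the sparseness grid search."""

    s_star: float
    cv_correlation: float
    path: list = field(default_factory=list)  # (s, cv_r) pairs


def _top_k(values: np.ndarray, k: int) -> np.ndarray:
    idx = np.argpartition(np.abs(values), len(values) - k)[-k:]
    return np.sort(idx)


def sccan_fit(
    X,
    y: np.ndarray,
    s: float,
    max_iter: int = 100,
    standardize: bool = True,
) -> SparseWeightMap:
    """Fit a sparse weight map at a fixed sparseness value.

    Voxel columns are standardized inside the solver (``standardize=True``,
    the default), so the initial gradient ranks voxels by their score
    *correlation* rather than covariance; on dTLVC data this keeps the
    truncation from preferentially retaining high-variance voxels.  At
    ``s = 1`` the constraint is inactive and ``w`` is proportional to the
    gradient ``X^T y`` of the (standardized, centered) design.  The
    returned weights have unit L2 norm and are oriented so that the
    projection correlates *negatively* with the score (damage predicts
    deficit); downstream consumers use the support.
    """
    Xv, mask = _design(X)
    y = np.asarray(y, dtype=float)
    n, p = Xv.shape
    if not 0 < s <= 1:
        raise ValueError("sparseness must be in (0, 1]")
    k = int(round(s * p))
    if k < 1:
        raise ValueError(
            f"sparseness {s:g} retains zero voxels on a {p}-voxel mask"
        )
    col_means = Xv.mean(axis=0)
    if standardize:
        sds = Xv.std(axis=0)
        col_sds = np.where(sds > 0, sds, np.inf)
    else:
        col_sds = np.ones(p)
    Z = (Xv - col_means) / col_sds
    yc = y - y.mean()

    g = Z.T @ yc
    support = _top_k(g, k)
    w = np.zeros(p)
    w[support] = g[support]
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        sub = Z[:, support]
        beta, *_ = np.linalg.lstsq(sub, yc, rcond=None)
        yhat = sub @ beta
        g = Z.T @ yhat
        new_support = _top_k(g, k)
        if np.array_equal(new_support, support):
            break
        support = new_support
        w = np.zeros(p)
        w[support] = g[support]

    norm = np.linalg.norm(w)
    if norm == 0:
        log.warning("degenerate fit: gradient vanished; uniform support weights")
        w[support] = 1.0
        norm = np.linalg.norm(w)
    w = w / norm
    proj = Z @ w
    c = float(proj @ yc)
    if c > 0:  # orient: damage -> lower scores
        w = -w
    return SparseWeightMap(
        weights=w,
        sparseness=float(s),
        support=support,
        mask=mask,
        column_means=col_means,
        column_sds=col_sds,
        n_iter=n_iter,
    )


def _fold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, k)]


def cv_correlation(
    X,
    y: np.ndarray,
    s: float,
    k: int = 4,
    rng: np.random.Generator | None = None,
    folds: list | None = None,
) -> float:
    """Cross-validated accuracy of the sparse solution at sparseness ``s``.

    Participants are split into ``k`` folds; for each fold the map is fit on
    the remaining participants and held-out scores are predicted as
    ``X_test w`` (sign-aligned to the training correlation).  Returns the
    Pearson correlation between pooled held-out predictions and observed
    scores.
    """
    Xv, _ = _design(X)
    y = np.asarray(y, dtype=float)
    n = Xv.shape[0]
    if folds is None:
        if not 2 <= k <= n:
            raise ValueError("need 2 <= k <= n folds")
        if rng is None:
            raise ValueError("rng required when folds are not supplied")
        folds = _fold_indices(n, k, rng)
    pred = np.empty(n)
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        fit = sccan_fit(Xv[train_idx], y[train_idx], s)
        proj_train = fit.project(Xv[train_idx])
        yc_train = y[train_idx] - y[train_idx].mean()
        sign = np.sign(proj_train @ yc_train)
        sign = sign if sign != 0 else 1.0
        pred[test_idx] = sign * fit.project(Xv[test_idx])
    if np.std(pred) == 0 or np.std(y) == 0:
        raise ValueError("pooled predictions or scores have zero variance")
    return float(np.corrcoef(pred, y)[0, 1])


def optimize_sparseness(
    X,
    y: np.ndarray,
    grid=DEFAULT_GRID,
    k: int = 4,
    tolerance: float = 0.02,
    rng: np.random.Generator | None = None,
    n_repeats: int = 3,
) -> SparsenessSearchResult:
    """Grid search for sparseness with a bias toward sparser solutions.

    The CV correlation for each grid value is averaged over ``n_repeats``
    independent k-fold splits (shared across the grid), which stabilizes
    the selection on small samples; the *smallest* ``s`` whose mean CV
    correlation is within ``tolerance`` of the maximum is selected.
    """
    grid = sorted(float(s) for s in grid)
    if not grid or not all(0 < s <= 1 for s in grid):
        raise ValueError("grid must contain values in (0, 1]")
    Xv, _ = _design(X)
    if rng is None:
        raise ValueError("rng required for fold assignment")
    foldsets = [
        _fold_indices(Xv.shape[0], k, rng) for _ in range(max(1, n_repeats))
    ]
    path = []
    for s in grid:
        rs = []
        for folds in foldsets:
            try:
                rs.append(cv_correlation(X, y, s, folds=folds))
            except ValueError:
                pass
        path.append((s, float(np.mean(rs)) if rs else np.nan))
    rs = np.array([r for _, r in path])
    if np.isnan(rs).all():
        raise ValueError("CV correlation undefined for every grid value")
    best = np.nanmax(rs)
    ok = np.flatnonzero(rs >= best - tolerance)
    s_star, r_star = path[ok[0]]
    return SparsenessSearchResult(
        s_star=s_star, cv_correlation=float(r_star), path=path
    )


def sccan_template(
    w: SparseWeightMap,
    provenance: str = "sccan",
    weight_threshold: float = 0.0,
) -> Template:
    """Binary template from the nonzero-weight support.

    ``weight_threshold`` optionally drops support voxels whose |weight| is
    below the given fraction of the maximum |weight| (default: any nonzero
    weight counts).
    """
    if w.mask is None:
        raise ValueError("weight map carries no analysis mask geometry")
    cols = w.support
    if weight_threshold > 0 and cols.size:
        mag = np.abs(w.weights[cols])
        cols = cols[mag >= weight_threshold * mag.max()]
    if cols.size == 0:
        log.info("SCCAN template is empty")
    return Template(
        geometry=w.mask.geometry,
        voxels=w.mask.voxel_index[cols],
        provenance=provenance,
    )


def spatial_majority_filter(
    template: Template, min_neighbors: int = 4
) -> Template:
    """Optional post-hoc spatial cleanup: keep voxels with enough 26-connected
    neighbors also in the template.  Off by default in every pipeline."""
    vol = template.to_volume()
    from scipy.ndimage import convolve

    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    counts = convolve(vol.astype(int), kernel, mode="constant")
    keep = vol & (counts >= min_neighbors)
    return Template(
        geometry=template.geometry,
        voxels=np.flatnonzero(keep.ravel()),
        provenance=template.provenance + "+majority",
    )
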