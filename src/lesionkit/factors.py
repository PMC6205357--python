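"""Battery reduction: PCA with varimax rotation and regression factor scores.

Multi-measure behavioral batteries (e.g. 17 psycholinguistic tests) are
reduced to a small number of orthogonal deficit factors: measures are
z-scored, the correlation matrix is eigendecomposed, components with
eigenvalue > 1 are retained (Kaiser rule, or an explicit count), and the
retained loadings are varimax-rotated with Kaiser row normalization.
Per-participant factor scores use the regression (Thurstone) method.

Rotation leaves each measure's communality and the total retained variance
unchanged; factor sign and order are indeterminate, so recovery checks go
through :func:`align_factors` / :func:`tucker_congruence`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "FactorModel",
    "fit_pca_varimax",
    "factor_scores",
    "varimax",
    "tucker_congruence",
    "align_factors",
]


def varimax(
    loadings: np.ndarray,
    normalize: bool = True,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation of a loading matrix.

    Maximizes the variance of squared loadings within each column, with
    Kaiser row normalization (rows scaled to unit communality during the
    rotation) by default.  Returns ``(rotated, rotation)`` with
    ``rotated = loadings @ rotation`` and ``rotation`` orthonormal.
    """
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    if k < 2:
        return L.copy(), np.eye(k)
    comm = np.sqrt((L**2).sum(axis=1))
    if normalize:
        safe = np.where(comm > 0, comm, 1.0)
        L = L / safe[:, None]
    R = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        B = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (B**3 - B @ np.diag((B**2).sum(axis=0)) / p)
        )
        R = u @ vt
        d = s.sum()
        if d_old != 0 and d < d_old * (1 + tol):
            break
        d_old = d
    rotated = L @ R
    if normalize:
        rotated = rotated * comm[:, None]
    return rotated, R


@dataclass
class FactorModel:
    """Fitted PCA + varimax model.

    Attributes
    ----------
    loadings : ndarray, measures x factors
        Post-rotation component loadings (correlations of measures with the
        rotated components).
    rotation : ndarray, factors x factors
        Orthonormal rotation applied to the retained unrotated loadings.
    eigenvalues : ndarray
        All eigenvalues of the measure correlation matrix, descending.
    variance_explained : ndarray
        Per-rotated-factor proportion of total variance.
    scores : ndarray, participants x factors
        Regression-method factor scores for the training battery.
    """

    loadings: np.ndarray
    rotation: np.ndarray
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    scores: np.ndarray
    measure_names: list
    means: np.ndarray
    sds: np.ndarray

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]


def _as_matrix(battery) -> tuple[np.ndarray, list]:
    if isinstance(battery, pd.DataFrame):
        return battery.to_numpy(dtype=float), list(battery.columns)
    arr = np.asarray(battery, dtype=float)
    return arr, [f"measure_{j + 1:02d}" for j in range(arr.shape[1])]


def fit_pca_varimax(battery, n_factors="kaiser") -> FactorModel:
    """Fit PCA with varimax rotation to a participants x measures battery.

    Parameters
    ----------
    battery : DataFrame or ndarray
        Numeric table, no missing values.
    n_factors : int or "kaiser"
        Number of components to retain; "kaiser" keeps eigenvalues > 1.0
        (so a component at 0.915 is dropped).
    """
    X, names = _as_matrix(battery)
    n, p = X.shape
    if np.isnan(X).any():
        raise ValueError("battery contains missing values")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if (sds == 0).any():
        bad = [names[j] for j in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant measure column(s): {bad}")
    Z = (X - means) / sds
    corr = (Z.T @ Z) / (n - 1)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.clip(vals[order], 0, None), vecs[:, order]

    if n_factors == "kaiser":
        k = int((vals > 1.0).sum())
        if k == 0:
            raise ValueError("no eigenvalue exceeds 1.0; nothing retained")
    else:
        k = int(n_factors)
        if k > p:
            raise ValueError(f"n_factors={k} exceeds {p} measures")
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} participants for {k} factors")

    unrotated = vecs[:, :k] * np.sqrt(vals[:k])
    rotated, R = varimax(unrotated)
    # order rotated factors by explained variance, descending
    var_per = (rotated**2).sum(axis=0)
    order_f = np.argsort(var_per)[::-1]
    rotated, R, var_per = rotated[:, order_f], R[:, order_f], var_per[order_f]

    model = FactorModel(
        loadings=rotated,
        rotation=R,
        eigenvalues=vals,
        variance_explained=var_per / p,
        scores=np.empty((0, k)),
        measure_names=names,
        means=means,
        sds=sds,
    )
    model.scores = factor_scores(model, battery)
    return model


def factor_scores(model: FactorModel, battery) -> np.ndarray:
    """Regression-method factor scores: Z @ corr^{-1} @ loadings.

    Columns are zero-mean for the training battery; new batteries are
    standardized with the model's stored means/SDs.
    """
    X, names = _as_matrix(battery)
    if names != model.measure_names:
        raise ValueError("battery columns do not match the fitted model")
    Z = (X - model.means) / model.sds
    W = getattr(model, "_weights", None)
    if W is None:
        # weight matrix from the scored battery's own correlation; at fit
        # time this is the training correlation matrix
        corr = np.corrcoef(Z, rowvar=False) if Z.shape[0] > 1 else np.eye(Z.shape[1])
        W = np.linalg.solve(corr, model.loadings)
        model._weights = W
    return Z @ W


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Tucker congruence (cosine similarity) between loading columns.

    Returns the factors(a) x factors(b) congruence matrix.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.linalg.norm(a, axis=0)
    nb = np.linalg.norm(b, axis=0)
    return (a.T @ b) / np.outer(na, nb)


def align_factors(
    estimated: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resolve sign/permutation indeterminacy against a reference.

    Finds the column permutation and signs of ``estimated`` maximizing the
    summed absolute Tucker congruence with ``reference`` (Hungarian
    assignment).  Returns ``(aligned, permutation, signs)`` where
    ``aligned[:, j]`` matches ``reference[:, j]``.
    """
    C = tucker_congruence(estimated, reference)
    rows, cols = linear_sum_assignment(-np.abs(C))
    perm = np.empty(len(cols), dtype=int)
    perm[cols] = rows
    signs = np.sign(C[perm, np.arange(len(perm))])
    signs[signs == 0] = 1.0
    aligned = estimated[:, perm] * signs
    return aligned, perm, signs
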