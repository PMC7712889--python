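"""Varimax-rotated PCA of experience and well-being reports.

The item battery (25 retrospective thought probes on a 1-4 Likert scale, or
questionnaire totals for well-being) is decomposed by PCA on the item
correlation matrix; components with eigenvalue > 1 are retained (Kaiser
criterion) and varimax-rotated with Kaiser row-normalisation. Component
scores are least-squares projections of the standardised items; regression
betas estimated in component space can be mapped back to item space through
the rotated loadings for interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor_rotation import rotate_factors

__all__ = ["ComponentModel", "pca_varimax", "back_project_betas", "varimax"]


@dataclass
class ComponentModel:
    """Rotated principal-component decomposition of an item battery."""

    loadings: np.ndarray  # items x k, varimax-rotated
    scores: np.ndarray  # subjects x k
    eigenvalues: np.ndarray  # all unrotated eigenvalues, descending
    n_retained: int
    variance_explained: np.ndarray  # per rotated component, fraction of total
    item_labels: list[str]

    @property
    def communalities(self) -> np.ndarray:
        return (self.loadings ** 2).sum(axis=1)


def varimax(loadings: np.ndarray, normalize: bool = True) -> np.ndarray:
    """Orthogonal varimax rotation with optional Kaiser row-normalisation.

    The sign of each rotated component is fixed so its largest-magnitude
    loading is positive.
    """
    L = np.asarray(loadings, dtype=float)
    if L.shape[1] == 1:
        rotated = L.copy()
    else:
        if normalize:
            h = np.sqrt((L ** 2).sum(axis=1))
            h[h == 0] = 1.0
            rotated, _ = rotate_factors(L / h[:, None], "varimax")
            rotated = rotated * h[:, None]
        else:
            rotated, _ = rotate_factors(L, "varimax")
    for j in range(rotated.shape[1]):
        if rotated[np.argmax(np.abs(rotated[:, j])), j] < 0:
            rotated[:, j] = -rotated[:, j]
    return rotated


def pca_varimax(reports) -> ComponentModel:
    """Correlation-matrix PCA with Kaiser retention and varimax rotation.

    Parameters
    ----------
    reports : DataFrame or (subjects, items) array
        Item scores; every item must have non-zero variance.

    Raises
    ------
    ValueError
        If an item is constant, fewer than 3 subjects are given, or no
        eigenvalue strictly exceeds 1 (nothing to retain).
    """
    if isinstance(reports, pd.DataFrame):
        labels = [str(c) for c in reports.columns]
        X = reports.to_numpy(dtype=float)
    else:
        X = np.asarray(reports, dtype=float)
        labels = [f"item_{j + 1:02d}" for j in range(X.shape[1])]
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    sd = X.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"constant item: {labels[dead[0]]}")
    Z = (X - X.mean(axis=0)) / sd

    R = np.corrcoef(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    k = int((eigvals > 1.0).sum())
    if k == 0:
        raise ValueError("no eigenvalue exceeds 1; nothing to retain")
    unrotated = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    loadings = varimax(unrotated)

    # least-squares projection of standardised items onto rotated loadings
    scores = Z @ loadings @ np.linalg.inv(loadings.T @ loadings)
    var_explained = (loadings ** 2).sum(axis=0) / p
    return ComponentModel(loadings=loadings, scores=scores, eigenvalues=eigvals,
                          n_retained=k, variance_explained=var_explained,
                          item_labels=labels)


def back_project_betas(betas_component_space: np.ndarray,
                       model: ComponentModel) -> np.ndarray:
    """Map component-space regression betas back to item space.

    betas_component_space : (n_predictors, k) — one row per predictor.
    Returns (n_predictors, items): betas x rotated loadings transposed.
    """
    B = np.atleast_2d(np.asarray(betas_component_space, dtype=float))
    if B.shape[1] != model.loadings.shape[1]:
        raise ValueError(
            f"expected {model.loadings.shape[1]} component betas, got {B.shape[1]}")
    return B @ model.loadings.T
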