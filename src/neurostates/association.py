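"""Multivariate association between state dwell-times and report components.

A multivariate multiple regression (MANCOVA) relates the per-subject
standardised mean dwell-times of the K states to the subjects' component
scores, with mean framewise displacement, age and gender as covariates of
no interest. Each dwell-time predictor is tested as a single-df
multivariate contrast with all other columns retained: Wilks'
Lambda = det(E) / det(E + H), where E is the residual SSCP matrix and H the
hypothesis SSCP of that coefficient row. For single-df hypotheses the F
approximation is exact:

    F = ((1 - Lambda) / Lambda) * (df2 / df1),
    df1 = p,  df2 = n - rank(X) - p + 1,

with p the number of outcome components, and partial eta^2 = 1 - Lambda.
No correction is applied across the K per-state tests (the count of tests
run is recorded on each result).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MancovaResult", "build_design_matrix", "fit_mancova"]


@dataclass
class MancovaResult:
    """Wilks test of one predictor in the multivariate regression."""

    predictor: str
    wilks_lambda: float
    f_stat: float
    df1: int
    df2: int
    p_value: float
    partial_eta_sq: float
    betas: np.ndarray  # (p,) outcome-space coefficients of this predictor
    n_tests_in_family: int = 1
    item_space_betas: np.ndarray | None = None


def build_design_matrix(dwell_std: np.ndarray, mean_fd: np.ndarray,
                        age: np.ndarray, gender: np.ndarray) -> pd.DataFrame:
    """Design: intercept, K standardised dwell-times, z-scored FD and age,
    binary gender."""
    dwell_std = np.asarray(dwell_std, dtype=float)
    n, K = dwell_std.shape

    def _z(x, name):
        x = np.asarray(x, dtype=float)
        sd = x.std()
        if sd == 0:
            raise ValueError(f"covariate {name} has zero variance")
        return (x - x.mean()) / sd

    cols = {"intercept": np.ones(n)}
    for s in range(K):
        cols[f"dwell_state_{s + 1}"] = dwell_std[:, s]
    cols["motion"] = _z(mean_fd, "motion")
    cols["age"] = _z(age, "age")
    cols["gender"] = np.asarray(gender, dtype=float)
    return pd.DataFrame(cols)


def fit_mancova(outcomes: np.ndarray, design: pd.DataFrame,
                predictors: list[str] | None = None) -> list[MancovaResult]:
    """Wilks' Lambda test of each dwell-time predictor.

    Parameters
    ----------
    outcomes : (n, p) component scores.
    design : DataFrame with named columns, including an intercept.
    predictors : columns to test (default: every ``dwell_state_*`` column).

    Returns one :class:`MancovaResult` per tested predictor.
    """
    Y = np.asarray(outcomes, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = design.to_numpy(dtype=float)
    n, p = Y.shape
    if X.shape[0] != n:
        raise ValueError("outcomes and design are not row-aligned")
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    df2 = n - r - p + 1
    if df2 < 1:
        raise ValueError(
            f"too few subjects: need n >= {r + p} for {p} outcomes "
            f"and rank-{r} design, got n = {n}")

    if predictors is None:
        predictors = [c for c in design.columns if c.startswith("dwell_state_")]
    missing = [c for c in predictors if c not in design.columns]
    if missing:
        raise ValueError(f"unknown design columns: {missing}")

    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y
    resid = Y - X @ B
    E = resid.T @ resid

    results = []
    col_index = {c: i for i, c in enumerate(design.columns)}
    for name in predictors:
        j = col_index[name]
        bj = B[j]
        H = np.outer(bj, bj) / XtX_inv[j, j]
        lam = float(np.linalg.det(E) / np.linalg.det(E + H))
        df1 = p
        f_stat = (1.0 - lam) / lam * (df2 / df1)
        p_value = float(stats.f.sf(f_stat, df1, df2))
        results.append(MancovaResult(
            predictor=name, wilks_lambda=lam, f_stat=float(f_stat),
            df1=df1, df2=int(df2), p_value=p_value,
            partial_eta_sq=1.0 - lam, betas=bj.copy(),
            n_tests_in_family=len(predictors)))
    return results
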