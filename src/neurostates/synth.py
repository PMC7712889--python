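"""Synthetic resting-state cohort generator.

Emulates the statistical structure the downstream analysis assumes, so the
whole pipeline is testable without access to scanner data:

* Markov-switching multivariate-Gaussian parcel time series with a known
  transition matrix and state means/covariances (the data-generating twin
  of the HMM that is later fitted);
* 25-item retrospective thought reports (1-4 Likert) whose latent component
  scores are linearly coupled to designated states' dwell-times with a
  configurable effect size;
* per-volume framewise-displacement (FD) motion traces with a configurable
  exceedance fraction, feeding the motion-exclusion rules;
* an orthogonal parcels x 3 gradient basis standing in for the first three
  connectivity gradients.

One global seed is expanded into per-subject substreams, so a given
subject's data are invariant to the cohort size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .hmm import mean_run_lengths

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "default_transition_matrix",
    "default_state_means",
    "generate_hmm_timeseries",
    "sample_state_paths",
    "generate_reports",
    "generate_gradient_basis",
    "generate_motion",
    "stationary_distribution",
    "write_dataset",
]


def default_transition_matrix(n_states: int, persistence: float = 0.88) -> np.ndarray:
    """Sticky transition matrix: ``persistence`` on the diagonal, the rest uniform."""
    if n_states == 1:
        return np.ones((1, 1))
    A = np.full((n_states, n_states), (1.0 - persistence) / (n_states - 1))
    np.fill_diagonal(A, persistence)
    return A


def default_state_means(n_states: int, n_parcels: int, amplitude: float = 0.8) -> np.ndarray:
    """Cosine (DCT-II) mean activity patterns, mutually distinct by construction.

    Amplitude is in standardised-parcel units (SD of the within-state noise).
    """
    s = np.arange(1, n_states + 1)[:, None]
    p = np.arange(n_parcels)[None, :]
    return amplitude * np.cos(np.pi * s * (2 * p + 1) / (2 * n_parcels))


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror the acquisition and cohort the analysis was designed
    for: 256 subjects, a 9-minute run at TR = 3 s (180 volumes), 17 network
    parcels, and a 7-state dynamic regime.
    """

    n_subjects: int = 256
    n_parcels: int = 17
    tr_seconds: float = 3.0
    scan_seconds: float = 540.0
    n_timepoints: int | None = None
    n_states: int = 7
    transition_matrix: np.ndarray | None = None
    state_means: np.ndarray | None = None
    state_covs: np.ndarray | None = None
    n_report_items: int = 25
    n_report_components: int = 8
    coupling_pairs: tuple = ((3, 1), (7, 2))  # (state, component), 1-based
    n_wellbeing_subjects: int = 168
    n_wellbeing_items: int = 10
    n_wellbeing_components: int = 3
    wellbeing_coupling_pairs: tuple = ((4, 1), (7, 2))
    report_effect_size: float = 0.5
    noise_sd: float = 1.0
    motion_mean_fd_mm: float = 0.15
    motion_bad_fraction: float = 0.02
    scrub_threshold_mm: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints is None:
            self.n_timepoints = int(self.scan_seconds // self.tr_seconds)
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if not (0.0 <= self.motion_bad_fraction <= 1.0):
            raise ValueError("motion_bad_fraction must lie in [0, 1]")
        if self.motion_mean_fd_mm < 0:
            raise ValueError("motion_mean_fd_mm must be non-negative")
        if not np.isfinite(self.report_effect_size):
            raise ValueError("report_effect_size must be finite")
        K, P = self.n_states, self.n_parcels
        if self.transition_matrix is None:
            self.transition_matrix = default_transition_matrix(K)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        rows = self.transition_matrix.sum(axis=1)
        if self.transition_matrix.shape != (K, K) or not np.allclose(rows, 1.0, atol=1e-12) \
                or (self.transition_matrix < 0).any():
            raise ValueError("transition_matrix must be K x K row-stochastic")
        if self.state_means is None:
            self.state_means = default_state_means(K, P)
        self.state_means = np.asarray(self.state_means, dtype=float)
        if self.state_means.shape != (K, P):
            raise ValueError("state_means must be K x P")
        if self.state_covs is None:
            self.state_covs = np.broadcast_to(np.eye(P), (K, P, P)).copy()
        self.state_covs = np.asarray(self.state_covs, dtype=float)
        for s in range(K):
            C = self.state_covs[s]
            if not np.allclose(C, C.T, atol=1e-10):
                raise ValueError(f"covariance of state {s + 1} is not symmetric")
            if np.linalg.eigvalsh(C).min() <= 0:
                raise ValueError(f"covariance of state {s + 1} is not positive-definite")

    def subject_ids(self) -> list[str]:
        return [f"sub-{i + 1:03d}" for i in range(self.n_subjects)]

    def _subject_rng(self, index: int, stream: int) -> np.random.Generator:
        # substream keyed by (subject, stream) so outputs are invariant to
        # cohort size and independent across generator products
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stream, index)))


@dataclass
class GroundTruth:
    """Recovery targets recorded while generating the cohort."""

    state_paths: list[np.ndarray]  # per subject, int in 1..K
    true_dwell_times: np.ndarray  # subjects x K, TRs (NaN where unvisited)
    true_component_scores: np.ndarray | None = None  # subjects x components
    report_loadings: np.ndarray | None = None  # items x components

    def to_json(self) -> dict:
        def _clean(a):
            return np.where(np.isfinite(a), a, None).tolist()
        out = {
            "state_paths": [p.tolist() for p in self.state_paths],
            "true_dwell_times": _clean(self.true_dwell_times),
        }
        if self.true_component_scores is not None:
            out["true_component_scores"] = self.true_component_scores.tolist()
        if self.report_loadings is not None:
            out["report_loadings"] = self.report_loadings.tolist()
        return out


def stationary_distribution(transition_matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of an ergodic chain (left eigenvector at 1)."""
    vals, vecs = np.linalg.eig(transition_matrix.T)
    i = np.argmin(np.abs(vals - 1.0))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _sample_path(rng: np.random.Generator, cum_A: np.ndarray, cum_pi: np.ndarray,
                 T: int) -> np.ndarray:
    """One Markov chain realisation (0-based) by inverse-CDF sampling."""
    u = rng.random(T)
    path = np.empty(T, dtype=int)
    path[0] = np.searchsorted(cum_pi, u[0], side="right")
    for t in range(1, T):
        path[t] = np.searchsorted(cum_A[path[t - 1]], u[t], side="right")
    return path


def sample_state_paths(config: SimulationConfig) -> GroundTruth:
    """Sample only the latent state paths (and their dwell-times).

    The initial state of each subject's chain is drawn from the stationary
    distribution of the transition matrix. Uses the same per-subject
    substreams as :func:`generate_hmm_timeseries`, so the paths agree.
    """
    K, T = config.n_states, config.n_timepoints
    A = config.transition_matrix
    pi = stationary_distribution(A)
    cum_A = np.cumsum(A, axis=1)
    cum_A[:, -1] = 1.0
    cum_pi = np.cumsum(pi)
    cum_pi[-1] = 1.0
    paths: list[np.ndarray] = []
    dwell = np.empty((config.n_subjects, K))
    for i in range(config.n_subjects):
        rng = config._subject_rng(i, stream=0)
        path1 = _sample_path(rng, cum_A, cum_pi, T) + 1
        paths.append(path1)
        dwell[i] = mean_run_lengths(path1, K)
    return GroundTruth(state_paths=paths, true_dwell_times=dwell)


def generate_hmm_timeseries(config: SimulationConfig):
    """Sample the cohort's parcel time series from the Markov-Gaussian model.

    The initial state of each subject's chain is drawn from the stationary
    distribution of the transition matrix. Returns
    (dict subject_id -> (T, P) array, GroundTruth).
    """
    K, P, T = config.n_states, config.n_parcels, config.n_timepoints
    A = config.transition_matrix
    pi = stationary_distribution(A)
    cum_A = np.cumsum(A, axis=1)
    cum_A[:, -1] = 1.0
    cum_pi = np.cumsum(pi)
    cum_pi[-1] = 1.0
    chols = np.linalg.cholesky(config.state_covs)
    series: dict[str, np.ndarray] = {}
    paths: list[np.ndarray] = []
    dwell = np.empty((config.n_subjects, K))
    for i, sid in enumerate(config.subject_ids()):
        rng = config._subject_rng(i, stream=0)
        path = _sample_path(rng, cum_A, cum_pi, T)
        z = rng.standard_normal((T, P))
        X = config.state_means[path] + np.einsum("tij,tj->ti", chols[path], z)
        path1 = path + 1
        series[sid] = X
        paths.append(path1)
        dwell[i] = mean_run_lengths(path1, K)
    return series, GroundTruth(state_paths=paths, true_dwell_times=dwell)


def _report_loadings(n_items: int, n_components: int) -> np.ndarray:
    """Fixed sparse loading pattern: items partitioned across components."""
    L = np.zeros((n_items, n_components))
    for j in range(n_items):
        L[j, j % n_components] = 0.9
    return L


def generate_reports(dwell_times: np.ndarray, config: SimulationConfig, *,
                     n_items: int | None = None, n_components: int | None = None,
                     coupling_pairs=None, stream: int = 1, likert: bool = True):
    """Report items coupled to dwell-times through latent components.

    Latent component scores are a linear combination of standardised
    dwell-times (coefficient ``report_effect_size`` on the designated
    (state, component) pairs, zero elsewhere) plus Gaussian noise with SD
    ``noise_sd``; items are the scores pushed through a fixed sparse loading
    pattern plus item noise, then discretised to 1-4 by quartile cut-points
    (``likert=True``, the experience battery) or rounded to questionnaire
    totals (``likert=False``, the well-being battery).

    Returns (items DataFrame (subjects x items), loadings
    (items x components), latent component scores).
    """
    dwell = np.asarray(dwell_times, dtype=float)
    if not np.isfinite(config.report_effect_size):
        raise ValueError("report_effect_size must be finite")
    n, K = dwell.shape
    n_items = config.n_report_items if n_items is None else n_items
    k = config.n_report_components if n_components is None else n_components
    coupling_pairs = config.coupling_pairs if coupling_pairs is None else coupling_pairs
    col_mean = np.nanmean(dwell, axis=0)
    col_sd = np.nanstd(dwell, axis=0)
    col_sd[col_sd == 0] = 1.0
    zd = (dwell - col_mean) / col_sd
    zd = np.where(np.isfinite(zd), zd, 0.0)

    coef = np.zeros((K, k))
    for state, comp in coupling_pairs:
        if 1 <= state <= K and 1 <= comp <= k:
            coef[state - 1, comp - 1] = config.report_effect_size

    rng_scores = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(stream,)))
    scores = zd @ coef + rng_scores.normal(0.0, config.noise_sd, size=(n, k))

    L = _report_loadings(n_items, k)
    rng_items = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(stream + 1,)))
    latent_items = scores @ L.T + rng_items.normal(0.0, 0.5, size=(n, n_items))
    if likert:
        items = np.empty_like(latent_items, dtype=int)
        for j in range(n_items):
            q = np.quantile(latent_items[:, j], [0.25, 0.5, 0.75])
            items[:, j] = 1 + np.searchsorted(q, latent_items[:, j], side="left")
    else:
        items = np.round(20.0 + 5.0 * latent_items).astype(int)
    df = pd.DataFrame(items, index=config.subject_ids()[:n],
                      columns=[f"item_{j + 1:02d}" for j in range(n_items)])
    df.index.name = "subject_id"
    return df, L, scores


def generate_gradient_basis(n_parcels: int, seed: int) -> np.ndarray:
    """Random orthogonal gradient basis: parcels x 3, zero-mean unit-norm columns."""
    if n_parcels < 3:
        raise ValueError("need at least 3 parcels for a 3-gradient basis")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    G = rng.standard_normal((n_parcels, 4))
    G -= G.mean(axis=0)
    Q, _ = np.linalg.qr(G)
    basis = Q[:, :3]
    # deterministic sign: largest-magnitude entry of each column positive
    for j in range(3):
        if basis[np.argmax(np.abs(basis[:, j])), j] < 0:
            basis[:, j] = -basis[:, j]
    return basis


def generate_motion(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Per-subject framewise-displacement traces (mm, one value per volume).

    FD is an i.i.d. gamma-mixture: with probability ``motion_bad_fraction``
    a volume exceeds the scrub threshold (threshold + exponential excess),
    otherwise it is a gamma draw whose mean is set so the overall expected
    mean equals ``motion_mean_fd_mm``.
    """
    f = config.motion_bad_fraction
    bad_mean = config.scrub_threshold_mm + 0.1
    if f >= 1.0:
        base_mean = 0.0
    else:
        base_mean = (config.motion_mean_fd_mm - f * bad_mean) / (1.0 - f)
    if base_mean < 0:
        raise ValueError(
            "motion_mean_fd_mm too small for the requested bad fraction")
    shape = 4.0
    traces = {}
    for i, sid in enumerate(config.subject_ids()):
        rng = config._subject_rng(i, stream=4)
        fd = rng.gamma(shape, base_mean / shape if base_mean > 0 else 1e-12,
                       size=config.n_timepoints)
        bad = rng.random(config.n_timepoints) < f
        fd[bad] = config.scrub_threshold_mm + rng.exponential(0.1, size=bad.sum())
        traces[sid] = fd
    return traces


# ---------------------------------------------------------------------------
# Disk layout: TSV time series, CSV reports/motion, TSV gradients, JSON truth

def write_dataset(config: SimulationConfig, out_dir: str | Path) -> Path:
    """Generate the full synthetic dataset and write it under ``out_dir``."""
    out = Path(out_dir)
    ts_dir = out / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    parcels = [f"parcel_{p + 1:02d}" for p in range(config.n_parcels)]

    series, truth = generate_hmm_timeseries(config)
    for sid, X in series.items():
        pd.DataFrame(X, columns=parcels).to_csv(
            ts_dir / f"{sid}.tsv", sep="\t", index=False, float_format="%.6f")

    reports, loadings, scores = generate_reports(truth.true_dwell_times, config)
    truth.true_component_scores = scores
    truth.report_loadings = loadings
    reports.to_csv(out / "reports.csv")

    n_wb = min(config.n_wellbeing_subjects, config.n_subjects)
    if n_wb >= 3:
        wellbeing, _, _ = generate_reports(
            truth.true_dwell_times[:n_wb], config,
            n_items=config.n_wellbeing_items,
            n_components=config.n_wellbeing_components,
            coupling_pairs=config.wellbeing_coupling_pairs,
            stream=6, likert=False)
        wellbeing.to_csv(out / "wellbeing.csv")

    motion = generate_motion(config)
    rows = [{"subject_id": sid, "volume": t, "fd_mm": fd[t]}
            for sid, fd in motion.items() for t in range(len(fd))]
    pd.DataFrame(rows).to_csv(out / "motion.csv", index=False,
                              float_format="%.6f")

    basis = generate_gradient_basis(config.n_parcels, config.seed)
    pd.DataFrame(basis, columns=["G1", "G2", "G3"]).to_csv(
        out / "gradients.tsv", sep="\t", index=False, float_format="%.8f")

    ages = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(5,)))
    cov = pd.DataFrame({
        "subject_id": config.subject_ids(),
        "age": np.round(ages.normal(20.7, 2.4, size=config.n_subjects), 1),
        "gender": ages.integers(0, 2, size=config.n_subjects),
    })
    cov.to_csv(out / "covariates.csv", index=False)

    (out / "ground_truth.json").write_text(json.dumps(truth.to_json()))
    return out
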