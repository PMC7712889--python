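"""Group-level Gaussian-observation hidden Markov model.

A single set of state parameters (mean activity map and covariance per
state, one transition matrix) is inferred from the concatenated group
matrix; state time courses are then decoded per subject. Inference is
multi-restart expectation-maximisation (Baum-Welch) with full-covariance
Gaussian emissions: each restart is initialised from k-means with a seeded
random perturbation, and the restart with the best final log-likelihood is
selected. Hard state assignment uses Viterbi decoding, from which the three
per-subject summary metrics are computed: mean dwell-time (in TRs),
fractional occupancy, and switching rate.

State labels in public outputs are 1-based (state 1..K), matching the
convention used when reporting brain states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

__all__ = [
    "HMMParams",
    "StateSequence",
    "StateMetrics",
    "fit_group_hmm",
    "log_likelihood",
    "viterbi_decode",
    "decode_states",
    "compute_state_metrics",
    "standardise_dwell_times",
    "match_states",
    "mean_run_lengths",
]

_COV_REG = 1e-6


@dataclass
class HMMParams:
    """Parameters of a K-state Gaussian-observation HMM.

    means : (K, P) state mean activity maps, in standardised parcel units.
    covariances : (K, P, P) symmetric positive-definite state covariances.
    transition_matrix : (K, K) row-stochastic.
    initial_probs : (K,) initial state distribution.
    objective_trace : per-iteration log-likelihood of the selected run
        (monotone non-decreasing up to numerical slack).
    """

    means: np.ndarray
    covariances: np.ndarray
    transition_matrix: np.ndarray
    initial_probs: np.ndarray
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True
    cov_regularised: bool = False

    @property
    def n_states(self) -> int:
        return self.means.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.means.shape[1]

    def validate(self) -> None:
        K, P = self.means.shape
        if self.covariances.shape != (K, P, P):
            raise ValueError("covariance shape mismatch")
        row_sums = self.transition_matrix.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-10):
            raise ValueError("transition matrix rows must sum to 1")
        for s in range(K):
            C = self.covariances[s]
            if not np.allclose(C, C.T, atol=1e-8):
                raise ValueError(f"covariance of state {s + 1} is not symmetric")
            if np.linalg.eigvalsh(C).min() <= 0:
                raise ValueError(f"covariance of state {s + 1} is not positive-definite")


@dataclass
class StateSequence:
    """Decoded state time course for one subject (states 1..K)."""

    subject_id: str
    posteriors: np.ndarray  # (T, K), rows sum to 1
    viterbi_path: np.ndarray  # (T,), int in 1..K


@dataclass
class StateMetrics:
    """Per-subject state summary metrics.

    mean_dwell_time : (n, K) average maximal-run length in TRs; NaN where a
        subject never visits a state (mean-imputed later at standardisation).
    fractional_occupancy : (n, K) proportion of TRs in each state.
    switching_rate : (n,) state changes per transition opportunity.
    """

    subject_ids: list[str]
    mean_dwell_time: np.ndarray
    fractional_occupancy: np.ndarray
    switching_rate: np.ndarray


# ---------------------------------------------------------------------------
# Emission densities

def _log_gaussian(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log density of N(mean, cov) at each row of X, via Cholesky."""
    P = X.shape[-1]
    L = np.linalg.cholesky(cov)
    diff = X - mean
    sol = np.linalg.solve(L, diff.reshape(-1, P).T).T
    maha = np.einsum("ij,ij->i", sol, sol)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    out = -0.5 * (P * np.log(2.0 * np.pi) + logdet + maha)
    return out.reshape(X.shape[:-1])


def _log_emissions(X: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """(..., P) observations -> (..., K) per-state log densities."""
    K = means.shape[0]
    out = np.empty(X.shape[:-1] + (K,))
    for s in range(K):
        out[..., s] = _log_gaussian(X, means[s], covs[s])
    return out


# ---------------------------------------------------------------------------
# Forward-backward (scaled, batched over subjects with equal length)

def _forward_backward(logB: np.ndarray, A: np.ndarray, pi: np.ndarray):
    """Scaled forward-backward for a batch of equal-length sequences.

    logB : (N, T, K) log emission densities.
    Returns (gamma (N,T,K), xi_sum (K,K), loglik (N,)).
    """
    N, T, K = logB.shape
    m = logB.max(axis=2, keepdims=True)
    Bt = np.exp(logB - m)  # in (0, 1]

    alpha = np.empty((N, T, K))
    c = np.empty((N, T))
    a = pi * Bt[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, T):
        a = (alpha[:, t - 1] @ A) * Bt[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t, None]

    beta = np.empty((N, T, K))
    beta[:, T - 1] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        w = Bt[:, t + 1] * beta[:, t + 1] / c[:, t + 1, None]  # (N, K)
        beta[:, t] = w @ A.T
        xi_sum += np.einsum("ni,nj->ij", alpha[:, t], w) * A

    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)
    loglik = np.log(c).sum(axis=1) + m[:, :, 0].sum(axis=1)
    return gamma, xi_sum, loglik


def _batched_sequences(sequences: list[np.ndarray]):
    """Group subject arrays by length for batched E-steps.

    Yields (indices, stacked (N_b, T, P)) per distinct length.
    """
    by_len: dict[int, list[int]] = {}
    for i, x in enumerate(sequences):
        by_len.setdefault(x.shape[0], []).append(i)
    for T, idx in sorted(by_len.items()):
        yield idx, np.stack([sequences[i] for i in idx])


def log_likelihood(params: HMMParams, X: np.ndarray) -> float:
    """Forward-pass log-likelihood of one observation sequence (T, P)."""
    logB = _log_emissions(X[None], params.means, params.covariances)
    _, _, ll = _forward_backward(logB, params.transition_matrix, params.initial_probs)
    return float(ll[0])


# ---------------------------------------------------------------------------
# Fitting

def _init_params(values: np.ndarray, K: int, rng: np.random.Generator,
                 perturb_sd: float = 0.1):
    km = KMeans(n_clusters=K, n_init=4,
                random_state=int(rng.integers(2**31 - 1))).fit(values)
    means = km.cluster_centers_ + rng.normal(0.0, perturb_sd, size=(K, values.shape[1]))
    P = values.shape[1]
    covs = np.empty((K, P, P))
    for s in range(K):
        pts = values[km.labels_ == s]
        if pts.shape[0] > P:
            covs[s] = np.cov(pts, rowvar=False) + _COV_REG * np.eye(P)
        else:
            covs[s] = np.cov(values, rowvar=False) + _COV_REG * np.eye(P)
    A = np.full((K, K), 0.1 / max(K - 1, 1))
    np.fill_diagonal(A, 0.9 if K > 1 else 1.0)
    pi = np.full(K, 1.0 / K)
    return means, covs, A, pi


def _em_run(sequences: list[np.ndarray], K: int, rng: np.random.Generator,
            max_iter: int, tol: float):
    values = np.concatenate(sequences, axis=0)
    P = values.shape[1]
    means, covs, A, pi = _init_params(values, K, rng)
    n_total = values.shape[0]
    trace = []
    converged = False
    reg_flag = False
    for _ in range(max_iter):
        Ngamma = np.zeros(K)
        sum_x = np.zeros((K, P))
        sum_xx = np.zeros((K, P, P))
        xi_sum = np.zeros((K, K))
        gamma0 = np.zeros(K)
        ll = 0.0
        for idx, X in _batched_sequences(sequences):
            logB = _log_emissions(X, means, covs)
            gamma, xi, lls = _forward_backward(logB, A, pi)
            ll += lls.sum()
            Ngamma += gamma.sum(axis=(0, 1))
            flatX = X.reshape(-1, P)
            flatG = gamma.reshape(-1, K)
            sum_x += flatG.T @ flatX
            sum_xx += np.einsum("nk,ni,nj->kij", flatG, flatX, flatX)
            xi_sum += xi
            gamma0 += gamma[:, 0].sum(axis=0)
        trace.append(ll)

        pi = gamma0 / len(sequences)
        if K > 1:
            A = xi_sum / xi_sum.sum(axis=1, keepdims=True)
        means = sum_x / Ngamma[:, None]
        reg_flag = False
        for s in range(K):
            C = sum_xx[s] / Ngamma[s] - np.outer(means[s], means[s])
            C = 0.5 * (C + C.T)
            if np.linalg.eigvalsh(C).min() <= 0:
                reg_flag = True
            covs[s] = C + _COV_REG * np.eye(P)

        if len(trace) >= 2:
            prev, cur = trace[-2], trace[-1]
            if abs(cur - prev) <= tol * (abs(prev) + 1e-12):
                converged = True
                break
    # final objective under the updated parameters
    ll = 0.0
    for idx, X in _batched_sequences(sequences):
        logB = _log_emissions(X, means, covs)
        _, _, lls = _forward_backward(logB, A, pi)
        ll += lls.sum()
    trace.append(ll)
    params = HMMParams(
        means=means, covariances=covs, transition_matrix=A, initial_probs=pi,
        objective_trace=np.asarray(trace), converged=converged,
        cov_regularised=reg_flag,
    )
    return params, ll, n_total


def fit_group_hmm(group, n_states: int, n_runs: int = 10, seed: int = 0,
                  max_iter: int = 500, tol: float = 1e-6,
                  return_all: bool = False):
    """Fit the group-level HMM with multiple restarts.

    Parameters
    ----------
    group : GroupMatrix or list of (T_i, P) arrays
        Standardised, concatenated parcel time series.
    n_states : int
        Number of states K.
    n_runs : int
        Independently initialised restarts; the run with the best final
        log-likelihood is returned, and every run's objective is reported
        for stability inspection.

    Returns
    -------
    (HMMParams, best_run_index, per_run_objectives), plus the list of every
    run's parameters when ``return_all`` is set (stability inspection).
    """
    if hasattr(group, "as_subject_arrays"):
        sequences = group.as_subject_arrays()
    else:
        sequences = [np.asarray(x, dtype=float) for x in group]
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    n_rows = sum(x.shape[0] for x in sequences)
    if n_rows < n_states:
        raise ValueError("fewer observations than states")

    ss = np.random.SeedSequence(seed)
    objectives = np.empty(n_runs)
    all_params = []
    best = None
    for run, child in enumerate(ss.spawn(n_runs)):
        rng = np.random.default_rng(child)
        params, ll, _ = _em_run(sequences, n_states, rng, max_iter, tol)
        objectives[run] = ll
        all_params.append(params)
        if best is None or ll > best[1]:
            best = (params, ll, run)
    params, _, best_run = best
    if return_all:
        return params, best_run, objectives, all_params
    return params, best_run, objectives


# ---------------------------------------------------------------------------
# Decoding

def viterbi_decode(params: HMMParams, X: np.ndarray) -> np.ndarray:
    """Most probable state path for one standardised sequence (T, P).

    Returns an int array of states in 1..K. Ties are broken toward the
    lowest state index for deterministic output.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != params.n_parcels:
        raise ValueError(
            f"expected (T, {params.n_parcels}) observations, got {X.shape}")
    K = params.n_states
    logB = _log_emissions(X, params.means, params.covariances)
    with np.errstate(divide="ignore"):
        logA = np.log(params.transition_matrix)
        logpi = np.log(params.initial_probs)
    T = X.shape[0]
    delta = logpi + logB[0]
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logA  # (from, to)
        back[t] = np.argmax(cand, axis=0)  # first max = lowest index
        delta = cand[back[t], np.arange(K)] + logB[t]
    path = np.empty(T, dtype=int)
    path[T - 1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path + 1


def decode_states(params: HMMParams, sequences, subject_ids=None) -> list[StateSequence]:
    """Posterior state probabilities and Viterbi path per subject."""
    if hasattr(sequences, "as_subject_arrays"):
        if subject_ids is None:
            subject_ids = sequences.retained_ids
        sequences = sequences.as_subject_arrays()
    if subject_ids is None:
        subject_ids = [f"sub-{i + 1:03d}" for i in range(len(sequences))]
    out = []
    for sid, X in zip(subject_ids, sequences):
        logB = _log_emissions(np.asarray(X, float)[None],
                              params.means, params.covariances)
        gamma, _, _ = _forward_backward(
            logB, params.transition_matrix, params.initial_probs)
        out.append(StateSequence(subject_id=sid, posteriors=gamma[0],
                                 viterbi_path=viterbi_decode(params, X)))
    return out


# ---------------------------------------------------------------------------
# Metrics

def mean_run_lengths(path: np.ndarray, n_states: int) -> np.ndarray:
    """Mean maximal-run length (TRs) per state; NaN for unvisited states.

    Truncated runs at the start and end of the path count as visits.
    """
    path = np.asarray(path)
    if path.size == 0:
        raise ValueError("empty path")
    change = np.flatnonzero(path[1:] != path[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [path.size]))
    out = np.full(n_states, np.nan)
    lengths = ends - starts
    labels = path[starts]
    for s in range(1, n_states + 1):
        runs = lengths[labels == s]
        if runs.size:
            out[s - 1] = runs.mean()
    return out


def compute_state_metrics(paths, n_states: int, subject_ids=None) -> StateMetrics:
    """Dwell-time, fractional occupancy and switching rate from Viterbi paths.

    paths : list of per-subject int arrays with states in 1..n_states.
    """
    if len(paths) == 0:
        raise ValueError("no paths given")
    if subject_ids is None:
        subject_ids = [f"sub-{i + 1:03d}" for i in range(len(paths))]
    n = len(paths)
    dwell = np.empty((n, n_states))
    occ = np.empty((n, n_states))
    switch = np.empty(n)
    for i, path in enumerate(paths):
        path = np.asarray(path)
        if path.size == 0:
            raise ValueError(f"empty path for subject {subject_ids[i]}")
        dwell[i] = mean_run_lengths(path, n_states)
        occ[i] = np.bincount(path - 1, minlength=n_states) / path.size
        switch[i] = (np.count_nonzero(path[1:] != path[:-1]) / (path.size - 1)
                     if path.size > 1 else 0.0)
    return StateMetrics(subject_ids=list(subject_ids), mean_dwell_time=dwell,
                        fractional_occupancy=occ, switching_rate=switch)


def standardise_dwell_times(dwell: np.ndarray, sigma: float = 2.5) -> np.ndarray:
    """Z-score dwell-times across subjects and null out |z| > sigma outliers.

    Per state, dwell-times are standardised across subjects (population SD);
    any value beyond ``sigma`` standard deviations is substituted with the
    mean (0 after standardisation). Missing entries (states a subject never
    visited) are likewise mean-imputed to 0.
    """
    dwell = np.asarray(dwell, dtype=float)
    if dwell.ndim != 2 or dwell.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    out = np.empty_like(dwell)
    for s in range(dwell.shape[1]):
        col = dwell[:, s]
        finite = np.isfinite(col)
        sd = np.std(col[finite])
        if sd == 0:
            raise ValueError(f"zero dwell-time variance for state {s + 1}")
        z = (col - col[finite].mean()) / sd
        z[~finite] = 0.0
        z[np.abs(z) > sigma] = 0.0
        out[:, s] = z
    return out


def match_states(a: HMMParams, b: HMMParams):
    """Optimal one-to-one matching of two solutions' state mean maps.

    Returns (perm, corrs): state i of ``a`` is paired with state perm[i] of
    ``b`` (0-based), maximising the summed Pearson correlation between mean
    maps; corrs[i] is the correlation of the matched pair.
    """
    if a.n_states != b.n_states or a.n_parcels != b.n_parcels:
        raise ValueError("state or parcel count mismatch")
    K = a.n_states
    za = (a.means - a.means.mean(axis=1, keepdims=True))
    zb = (b.means - b.means.mean(axis=1, keepdims=True))
    if (np.linalg.norm(za, axis=1) == 0).any() or \
            (np.linalg.norm(zb, axis=1) == 0).any():
        # constant maps have undefined Pearson correlation; fall back to
        # cosine similarity of the raw maps
        za, zb = a.means.copy(), b.means.copy()
    za /= np.linalg.norm(za, axis=1, keepdims=True)
    zb /= np.linalg.norm(zb, axis=1, keepdims=True)
    corr = za @ zb.T
    rows, cols = linear_sum_assignment(-corr)
    perm = np.empty(K, dtype=int)
    perm[rows] = cols
    return perm, corr[rows, cols]
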