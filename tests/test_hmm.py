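"""HMM inference, decoding and state metrics.

Viterbi is checked against exhaustive path enumeration, the forward pass
and decoding against hmmlearn given identical parameters, and parameter
recovery against the generating model of the synthetic cohort.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import multivariate_normal

from neurostates.hmm import (HMMParams, compute_state_metrics, decode_states,
                             fit_group_hmm, log_likelihood, match_states,
                             mean_run_lengths, standardise_dwell_times,
                             viterbi_decode)
from neurostates.synth import SimulationConfig, generate_hmm_timeseries


def _toy_params(rng, K=2, P=2):
    means = rng.normal(0, 2, size=(K, P))
    covs = np.empty((K, P, P))
    for s in range(K):
        M = rng.normal(size=(P, P))
        covs[s] = M @ M.T + np.eye(P)
    A = rng.dirichlet(np.ones(K) * 3, size=K)
    pi = rng.dirichlet(np.ones(K))
    return HMMParams(means=means, covariances=covs, transition_matrix=A,
                     initial_probs=pi)


def _brute_force_viterbi(params, X):
    """Exhaustive maximisation over all K^T paths (independent oracle)."""
    K, T = params.n_states, X.shape[0]
    logB = np.stack([multivariate_normal.logpdf(X, params.means[s],
                                                params.covariances[s])
                     for s in range(K)], axis=1)
    logA = np.log(params.transition_matrix)
    logpi = np.log(params.initial_probs)
    best_path, best_lp = None, -np.inf
    for path in itertools.product(range(K), repeat=T):
        lp = logpi[path[0]] + logB[0, path[0]]
        for t in range(1, T):
            lp += logA[path[t - 1], path[t]] + logB[t, path[t]]
        if lp > best_lp:
            best_path, best_lp = path, lp
    return np.asarray(best_path) + 1


class TestViterbi:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        params = _toy_params(rng)
        X = rng.normal(0, 2, size=(6, 2))
        assert np.array_equal(viterbi_decode(params, X),
                              _brute_force_viterbi(params, X))

    def test_single_state_path_is_constant(self, rng):
        params = HMMParams(means=np.zeros((1, 3)),
                           covariances=np.eye(3)[None],
                           transition_matrix=np.ones((1, 1)),
                           initial_probs=np.ones(1))
        path = viterbi_decode(params, rng.standard_normal((20, 3)))
        assert np.all(path == 1)

    def test_identical_states_tie_break_to_lowest_index(self, rng):
        params = HMMParams(means=np.zeros((2, 2)),
                           covariances=np.stack([np.eye(2)] * 2),
                           transition_matrix=np.full((2, 2), 0.5),
                           initial_probs=np.array([0.5, 0.5]))
        path = viterbi_decode(params, rng.standard_normal((15, 2)))
        assert np.all(path == 1)

    def test_dimension_mismatch_rejected(self, rng):
        params = _toy_params(rng, K=2, P=3)
        with pytest.raises(ValueError):
            viterbi_decode(params, rng.standard_normal((10, 4)))


class TestHmmlearnOracle:
    """Given identical parameters, our forward pass and Viterbi must agree
    with hmmlearn's (an independent implementation)."""

    def test_loglik_and_viterbi_agree(self, rng):
        from hmmlearn.hmm import GaussianHMM
        params = _toy_params(rng, K=3, P=4)
        X = rng.normal(0, 2, size=(200, 4))
        ref = GaussianHMM(n_components=3, covariance_type="full",
                          init_params="")
        ref.startprob_ = params.initial_probs
        ref.transmat_ = params.transition_matrix
        ref.means_ = params.means
        ref.covars_ = params.covariances
        assert log_likelihood(params, X) == pytest.approx(ref.score(X),
                                                          rel=1e-9)
        assert np.array_equal(viterbi_decode(params, X), ref.predict(X) + 1)


class TestFit:
    def test_two_state_parameter_recovery(self):
        cfg = SimulationConfig(
            n_subjects=20, n_timepoints=200, n_parcels=4, n_states=2,
            transition_matrix=[[0.9, 0.1], [0.1, 0.9]],
            state_means=np.vstack([2 * np.ones(4), -2 * np.ones(4)]),
            seed=13)
        series, _ = generate_hmm_timeseries(cfg)
        params, _, _ = fit_group_hmm(list(series.values()), 2, n_runs=2,
                                     seed=0, max_iter=200)
        truth = HMMParams(means=cfg.state_means, covariances=cfg.state_covs,
                          transition_matrix=cfg.transition_matrix,
                          initial_probs=np.full(2, 0.5))
        perm, corrs = match_states(truth, params)
        assert np.abs(params.means[perm] - truth.means).max() < 0.1
        assert np.abs(params.transition_matrix[np.ix_(perm, perm)]
                      - truth.transition_matrix).max() < 0.05

    def test_multi_restart_stability_on_separated_data(self):
        cfg = SimulationConfig(
            n_subjects=10, n_timepoints=150, n_parcels=3, n_states=2,
            state_means=np.vstack([3 * np.ones(3), -3 * np.ones(3)]), seed=4)
        series, _ = generate_hmm_timeseries(cfg)
        best, best_run, objs, all_params = fit_group_hmm(
            list(series.values()), 2, n_runs=10, seed=1, max_iter=100,
            return_all=True)
        assert objs[best_run] >= objs.max() - 1e-9  # selection contract
        for p in all_params:
            _, corrs = match_states(best, p)
            assert corrs.min() > 0.99

    def test_single_state_degenerate_fit(self, rng):
        X = rng.standard_normal((500, 3)) * 1.7 + [0.0, 1.0, -1.0]
        params, _, _ = fit_group_hmm([X], 1, n_runs=1, seed=0)
        assert np.allclose(params.means[0], X.mean(axis=0), atol=1e-8)
        assert np.allclose(params.covariances[0],
                           np.cov(X, rowvar=False, ddof=0), atol=1e-5)
        assert np.all(viterbi_decode(params, X) == 1)

    def test_objective_trace_is_monotone(self):
        cfg = SimulationConfig(n_subjects=6, n_timepoints=100, n_parcels=3,
                               n_states=2, seed=2)
        series, _ = generate_hmm_timeseries(cfg)
        params, _, _ = fit_group_hmm(list(series.values()), 2, n_runs=1,
                                     seed=5, max_iter=100)
        trace = params.objective_trace
        assert np.all(np.diff(trace) >= -1e-8 * np.abs(trace[:-1]))

    def test_posterior_viterbi_agreement_under_strong_separation(self):
        cfg = SimulationConfig(
            n_subjects=5, n_timepoints=150, n_parcels=3, n_states=2,
            state_means=np.vstack([5 * np.ones(3), -5 * np.ones(3)]), seed=8)
        series, _ = generate_hmm_timeseries(cfg)
        params, _, _ = fit_group_hmm(list(series.values()), 2, n_runs=1,
                                     seed=0)
        seqs = decode_states(params, list(series.values()))
        agree = np.concatenate([
            s.viterbi_path == (np.argmax(s.posteriors, axis=1) + 1)
            for s in seqs])
        assert agree.mean() >= 0.99
        for s in seqs:
            assert np.allclose(s.posteriors.sum(axis=1), 1.0, atol=1e-8)


class TestStateMetrics:
    def test_printed_toy_path(self):
        m = compute_state_metrics([np.array([1, 1, 2, 2, 2, 1])], 2)
        assert m.mean_dwell_time[0, 0] == pytest.approx(1.5)
        assert m.mean_dwell_time[0, 1] == pytest.approx(3.0)
        assert np.allclose(m.fractional_occupancy[0], [0.5, 0.5])
        assert m.switching_rate[0] == pytest.approx(2 / 5)

    def test_constant_path(self):
        m = compute_state_metrics([np.full(30, 2)], 3)
        assert m.mean_dwell_time[0, 1] == 30
        assert np.isnan(m.mean_dwell_time[0, 0])
        assert m.fractional_occupancy[0, 1] == 1.0
        assert m.switching_rate[0] == 0.0

    def test_alternating_path(self):
        path = np.tile([1, 2], 10)
        m = compute_state_metrics([path], 2)
        assert np.all(m.mean_dwell_time[0] == 1.0)
        assert m.switching_rate[0] == 1.0

    @given(st.lists(st.integers(1, 3), min_size=2, max_size=60))
    def test_occupancy_times_T_partitions_the_path(self, path):
        path = np.asarray(path)
        m = compute_state_metrics([path], 3)
        counts = m.fractional_occupancy[0] * path.size
        assert np.allclose(counts.sum(), path.size)
        assert np.allclose(counts, np.round(counts))
        # dwell-time of visited states is at least 1 TR
        visited = np.isfinite(m.mean_dwell_time[0])
        assert np.all(m.mean_dwell_time[0][visited] >= 1.0)
        assert 0.0 <= m.switching_rate[0] <= 1.0

    def test_empty_path_rejected(self):
        with pytest.raises(ValueError):
            compute_state_metrics([np.array([], dtype=int)], 2)


class TestDwellStandardisation:
    def test_plain_zscores_when_no_outliers(self, rng):
        d = rng.normal(10, 2, size=(40, 3))
        z = standardise_dwell_times(d)
        expected = (d - d.mean(axis=0)) / d.std(axis=0)
        expected[np.abs(expected) > 2.5] = 0.0
        assert np.allclose(z, expected)
        assert np.abs(z.mean(axis=0)).max() < 0.5

    def test_injected_extreme_value_becomes_zero(self, rng):
        d = rng.normal(10, 1, size=(50, 2))
        d[7, 0] = 10 + 6  # about 6 sigma
        z = standardise_dwell_times(d)
        assert z[7, 0] == 0.0

    def test_replacement_count_matches_independent_recount(self, rng):
        d = rng.standard_t(df=3, size=(200, 4)) * 2 + 8
        z = standardise_dwell_times(d)
        expected_zeroed = 0
        for s in range(4):
            col = (d[:, s] - d[:, s].mean()) / d[:, s].std()
            expected_zeroed += int((np.abs(col) > 2.5).sum())
        assert int((z == 0).sum()) == expected_zeroed

    def test_missing_dwell_times_imputed_to_mean(self, rng):
        d = rng.normal(5, 1, size=(10, 2))
        d[3, 1] = np.nan
        z = standardise_dwell_times(d)
        assert z[3, 1] == 0.0

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            standardise_dwell_times(np.ones((2, 3)))


class TestMatchStates:
    def _params(self, means):
        K, P = means.shape
        return HMMParams(means=means, covariances=np.stack([np.eye(P)] * K),
                         transition_matrix=np.full((K, K), 1 / K),
                         initial_probs=np.full(K, 1 / K))

    def test_relabelling_recovered(self, rng):
        means = rng.standard_normal((4, 6))
        perm_true = np.array([2, 0, 3, 1])
        a = self._params(means)
        b = self._params(means[perm_true])
        perm, corrs = match_states(a, b)
        # state i of a sits at position argwhere(perm_true == i) in b
        assert np.array_equal(perm_true[perm], np.arange(4))
        assert np.allclose(corrs, 1.0)

    def test_identity(self, rng):
        a = self._params(rng.standard_normal((3, 5)))
        perm, corrs = match_states(a, a)
        assert np.array_equal(perm, np.arange(3))
        assert np.allclose(corrs, 1.0)

    def test_independent_maps_match_poorly(self):
        # Monte-Carlo null: unrelated K=7, P=17 maps rarely align well
        rng = np.random.default_rng(99)
        mean_corrs = []
        for _ in range(200):
            a = self._params(rng.standard_normal((7, 17)))
            b = self._params(rng.standard_normal((7, 17)))
            _, corrs = match_states(a, b)
            mean_corrs.append(corrs.mean())
        assert np.mean(mean_corrs) < 0.8

    def test_state_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            match_states(self._params(rng.standard_normal((3, 5))),
                         self._params(rng.standard_normal((4, 5))))


def test_mean_run_lengths_counts_truncated_runs():
    # runs cut by the start/end of the path still count as visits
    out = mean_run_lengths(np.array([2, 2, 1, 1, 1, 2]), 2)
    assert out[0] == 3.0  # single interior run of state 1
    assert out[1] == 1.5  # truncated runs of length 2 and 1
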