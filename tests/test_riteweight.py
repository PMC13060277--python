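import numpy as np
import pytest

from ensrect.riteweight import (
    ReducibleChainError,
    RWConfig,
    TransitionSet,
    collect_transitions,
    rw_diagnostics,
    rw_diagnostics_trace,
    rw_iterate,
    stationary_distribution,
)
from ensrect.synthetic_systems import markov_chain_transitions

THREE_STATE_T = np.array([
    [0.80, 0.15, 0.05],
    [0.10, 0.80, 0.10],
    [0.05, 0.25, 0.70],
])
CENTERS_3 = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])


def analytic_stationary(T):
    """Null-space solve of (T' - I) pi = 0 — independent of the package path."""
    n = T.shape[0]
    A = np.vstack([T.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return pi


def aggregate_by_state(ts, weights, centers):
    d2 = ((ts.end[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    states = np.argmin(d2, axis=1)
    return np.bincount(states, weights=weights, minlength=len(centers))


class TestStationaryDistribution:
    def test_two_state_analytic_balance(self):
        T = np.array([[0.9, 0.1], [0.5, 0.5]])
        pi = stationary_distribution(T)
        np.testing.assert_allclose(pi, [5 / 6, 1 / 6], atol=1e-10)

    def test_identity_matrix_is_reducible(self):
        with pytest.raises(ReducibleChainError):
            stationary_distribution(np.eye(2))

    def test_block_diagonal_is_reducible(self):
        T = np.array([
            [0.5, 0.5, 0.0, 0.0],
            [0.5, 0.5, 0.0, 0.0],
            [0.0, 0.0, 0.9, 0.1],
            [0.0, 0.0, 0.1, 0.9],
        ])
        with pytest.raises(ReducibleChainError):
            stationary_distribution(T)

    def test_random_chain_matches_power_iteration(self, rng):
        T = rng.random((5, 5)) + 0.05
        T /= T.sum(axis=1, keepdims=True)
        pi = stationary_distribution(T)
        # independent oracle: long power iteration
        v = np.full(5, 0.2)
        for _ in range(10_000):
            v = v @ T
        np.testing.assert_allclose(pi, v, atol=1e-10)

    def test_non_stochastic_rejected(self):
        with pytest.raises(ValueError):
            stationary_distribution(np.array([[0.9, 0.2], [0.5, 0.5]]))


class TestTransitionSet:
    def test_weights_renormalized(self):
        ts = TransitionSet(
            start=np.zeros((4, 1)), end=np.ones((4, 1)), weights=np.full(4, 2.0)
        )
        assert ts.weights.sum() == pytest.approx(1.0)

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError):
            TransitionSet(
                start=np.zeros((2, 1)), end=np.ones((2, 1)),
                weights=np.array([1.0, 0.0]),
            )


class TestCollectTransitions:
    def _history(self):
        from ensrect.grid_downsample import GridSpec
        from ensrect.synthetic_systems import double_well
        from ensrect.we_engine import OverdampedLangevin, WEConfig, run_we

        pot = double_well(3.0)
        prop = OverdampedLangevin(pot, dt=0.01)
        grid = GridSpec(edges=[np.linspace(-3, 3, 7)] * 2, n_core_bins=[6, 6])
        states = [np.array([-1.0, 0.0]), np.array([1.0, 0.0]), np.array([0.0, 0.5])]
        return run_we(states, np.full(3, 1 / 3), prop, grid,
                      WEConfig(tau=0.2, target_per_bin=2, n_iterations=5, seed=2))

    def test_one_segment_per_walker_per_iteration(self):
        hist = self._history()
        ts = collect_transitions(hist)
        assert ts.n_segments == sum(r.n_walkers for r in hist.iterations)

    def test_weights_match_history_records(self):
        hist = self._history()
        ts = collect_transitions(hist)
        raw = np.concatenate([r.weights for r in hist.iterations])
        np.testing.assert_allclose(ts.weights, raw / raw.sum(), atol=1e-12)

    def test_empty_history_rejected(self):
        from ensrect.grid_downsample import GridSpec
        from ensrect.we_engine import WEConfig, WEHistory

        empty = WEHistory(
            iterations=[],
            grid=GridSpec(edges=[np.linspace(0, 1, 3)], n_core_bins=[2]),
            config=WEConfig(tau=1.0),
        )
        with pytest.raises(ValueError):
            collect_transitions(empty)

    def test_retained_dims_truncated_by_space(self):
        from ensrect.ensemble_geometry import PCSpace

        hist = self._history()
        space = PCSpace(
            reference=np.zeros((2, 3)), mean_coords=np.zeros(6),
            axes=np.eye(6), variance_fractions=np.array([0.9, 0.1]),
            n_retained=1,
        )
        ts = collect_transitions(hist, space)
        assert ts.n_dims == 1


class TestRwIterate:
    def test_smoothing_one_gives_cluster_means(self):
        """In the s=1 limit every segment in a cluster carries the cluster mean."""
        ts = markov_chain_transitions(
            THREE_STATE_T, CENTERS_3, 3000, np.array([0.5, 0.3, 0.2]), seed=1
        )
        cfg = RWConfig(n_clusters=2, n_iterations=1, smoothing=1.0, seed=3)
        res = rw_iterate(ts, cfg)
        # group final weights by end point cluster: each group must be constant
        vals = np.round(res.final_weights, 14)
        assert len(np.unique(vals)) <= 2

    def test_zero_smoothing_reproduces_raw_update(self):
        """One iteration with s=0 equals the hand-computed raw rescaling."""
        ts = markov_chain_transitions(
            THREE_STATE_T, CENTERS_3, 2000, np.array([1, 1, 1]) / 3, seed=5
        )
        cfg = RWConfig(n_clusters=2, n_iterations=1, smoothing=0.0, seed=11)
        res = rw_iterate(ts, cfg)
        # replay the same clustering stream by hand
        from ensrect.riteweight import _assign_to_centers, _kmeans_partition

        rng = np.random.default_rng(np.random.SeedSequence([11, 0x52575F]))
        labels_end, centers = _kmeans_partition(ts.end, 2, rng, cfg.kmeans_steps)
        labels_start = _assign_to_centers(ts.start, centers)
        w = ts.weights
        w_start = np.bincount(labels_start, weights=w, minlength=2)
        flow = np.zeros((2, 2))
        np.add.at(flow, (labels_start, labels_end), w)
        pi = stationary_distribution(flow / w_start[:, None])
        raw = w * (pi / w_start)[labels_start]
        raw /= raw.sum()
        np.testing.assert_allclose(res.final_weights, raw, atol=1e-12)

    def test_normalization_preserved_every_iteration(self):
        ts = markov_chain_transitions(
            THREE_STATE_T, CENTERS_3, 2000, np.array([0.1, 0.1, 0.8]), seed=2
        )
        cfg = RWConfig(n_clusters=2, n_iterations=50, smoothing=0.01, seed=0)
        res = rw_iterate(ts, cfg)
        assert abs(res.final_weights.sum() - 1.0) < 1e-9

    def test_stationary_start_is_near_fixed_point(self):
        """Transitions sampled at stationarity with stationary weights barely move."""
        T = np.array([[0.9, 0.1], [0.3, 0.7]])
        centers = np.array([[0.0, 0.0], [1.5, 0.0]])
        pi = analytic_stationary(T)
        ts = markov_chain_transitions(T, centers, 10_000, pi, seed=4)
        cfg = RWConfig(n_clusters=2, n_iterations=500, smoothing=0.01, seed=6)
        res = rw_iterate(ts, cfg)
        assert res.weight_trace.mean() < 1e-2

    def test_biased_initial_weights_recover_stationary(self):
        """Uniform (wrong) initial weights converge to the analytic stationary
        vector of the generating chain, aggregated by end state."""
        pi = analytic_stationary(THREE_STATE_T)
        ts = markov_chain_transitions(
            THREE_STATE_T, CENTERS_3, 10_000, np.full(3, 1 / 3), seed=8
        )
        cfg = RWConfig(n_clusters=2, n_iterations=800, smoothing=0.01, seed=9,
                       avg_window=100)
        res = rw_iterate(ts, cfg)
        pops = aggregate_by_state(ts, res.final_weights, CENTERS_3)
        np.testing.assert_allclose(pops, pi, atol=0.02)

    def test_cluster_count_robustness(self):
        """Final aggregated populations agree between 2 and 3 clusters."""
        T = np.array([[0.9, 0.1], [0.3, 0.7]])
        centers = np.array([[0.0, 0.0], [1.5, 0.0]])
        pi = analytic_stationary(T)
        ts = markov_chain_transitions(T, centers, 8000, np.array([0.9, 0.1]), seed=3)
        pops = {}
        for k in (2, 3):
            cfg = RWConfig(n_clusters=k, n_iterations=600, smoothing=0.01,
                           seed=10, avg_window=100)
            res = rw_iterate(ts, cfg)
            pops[k] = aggregate_by_state(ts, res.final_weights, centers)
        np.testing.assert_allclose(pops[2], pops[3], atol=0.03)
        np.testing.assert_allclose(pops[2], pi, atol=0.03)

    def test_too_few_distinct_endpoints_rejected(self):
        ts = TransitionSet(
            start=np.zeros((5, 1)), end=np.zeros((5, 1)), weights=np.full(5, 0.2)
        )
        with pytest.raises(ValueError):
            rw_iterate(ts, RWConfig(n_clusters=2, n_iterations=1))

    def test_disconnected_transitions_raise_after_retries(self):
        # two states that never interconvert -> every clustering is reducible
        T = np.eye(2)
        centers = np.array([[0.0, 0.0], [5.0, 0.0]])
        ts = markov_chain_transitions(T, centers, 400, np.array([0.5, 0.5]), seed=1)
        cfg = RWConfig(n_clusters=2, n_iterations=5, smoothing=0.01, seed=2,
                       retry_cap=5)
        with pytest.raises(ReducibleChainError):
            rw_iterate(ts, cfg)


class TestDiagnostics:
    def test_constant_weights_converged(self):
        trace = np.zeros(100)
        d = rw_diagnostics_trace(trace, window=10)
        assert d["converged"] and d["window_mean"] == 0.0

    def test_monotone_trace_window_below_global_mean(self):
        trace = np.linspace(1.0, 0.0, 200)
        d = rw_diagnostics_trace(trace, window=20)
        assert d["window_mean"] < d["global_mean"]

    def test_window_larger_than_trace_rejected(self):
        from ensrect.riteweight import RWResult

        res = RWResult(final_weights=np.array([1.0]), weight_trace=np.zeros(5),
                       converged=True)
        with pytest.raises(ValueError):
            rw_diagnostics(res, window=10)
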