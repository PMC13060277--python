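import math

import numpy as np
import pytest

from ensrect.grid_downsample import GridSpec, build_grid
from ensrect.synthetic_systems import biased_seed_ensemble, double_well
from ensrect.we_engine import (
    FrozenPropagator,
    OverdampedLangevin,
    Walker,
    WEConfig,
    WEHistory,
    extend_grid,
    resample,
    run_we,
    _walker_rng,
)


class HarmonicWell:
    """1D harmonic potential E = k x^2 / 2."""

    def __init__(self, k=1.0):
        self.k = k

    def energy(self, p):
        return 0.5 * self.k * np.asarray(p, float)[..., 0] ** 2

    def gradient(self, p):
        return self.k * np.asarray(p, float)


class TestExtendGrid:
    def test_extended_bin_count(self):
        grid = GridSpec(edges=[np.linspace(0, 1, 11)] * 2, n_core_bins=[10, 10])
        ext = extend_grid(grid, n_pad=5)
        assert ext.n_bins == [20, 20]
        assert ext.total_bins == 400

    def test_zero_pad_is_identity(self):
        grid = GridSpec(edges=[np.linspace(0, 1, 11)] * 2, n_core_bins=[10, 10])
        ext = extend_grid(grid, n_pad=0)
        for a, b in zip(ext.edges, grid.edges):
            np.testing.assert_array_equal(a, b)

    def test_pad_bins_keep_core_width(self):
        grid = GridSpec(edges=[np.linspace(-1.2, 2.6, 11)], n_core_bins=[10])
        ext = extend_grid(grid, n_pad=5)
        widths = np.diff(ext.edges[0])
        np.testing.assert_allclose(widths, widths[0], atol=1e-9)
        assert len(ext.edges[0]) == 21


class TestResample:
    def _walkers(self, weights):
        return [
            Walker(state=np.array([float(i), 0.0]), weight=w, parent_id=i, walker_id=i)
            for i, w in enumerate(weights)
        ]

    def test_single_walker_split_to_eight_equal(self, rng):
        out = resample(self._walkers([0.4]), target=8, rng=rng)
        assert len(out) == 8
        np.testing.assert_allclose([w.weight for w in out], 0.05)
        assert math.fsum(w.weight for w in out) == pytest.approx(0.4, abs=1e-15)

    def test_at_target_unchanged(self, rng):
        weights = [0.1, 0.2, 0.3, 0.05, 0.05, 0.1, 0.1, 0.1]
        out = resample(self._walkers(weights), target=8, rng=rng)
        assert sorted(w.weight for w in out) == sorted(weights)

    def test_weight_conserved_exactly(self, rng):
        for n, target in [(1, 8), (10, 8), (20, 3), (3, 16)]:
            weights = rng.random(n) + 0.01
            walkers = self._walkers(weights / weights.sum() * 0.37)
            before = math.fsum(w.weight for w in walkers)
            out = resample(walkers, target, rng)
            assert len(out) == target
            assert math.fsum(w.weight for w in out) == pytest.approx(before, abs=1e-15)

    def test_merge_survivor_unbiased(self):
        """Monte-Carlo: mean post-resampling weight of a marked subset equals
        its pre-resampling weight (statistical exactness of split/merge)."""
        base = np.random.default_rng(7).random(10) + 0.05
        base = base / base.sum()
        marked = {2, 5, 9}
        pre = sum(base[i] for i in marked)
        totals = []
        for seed in range(2000):
            rng = np.random.default_rng(seed)
            out = resample(self._walkers(base), target=8, rng=rng)
            totals.append(sum(w.weight for w in out if w.parent_id in marked))
        mean = np.mean(totals)
        se = np.std(totals, ddof=1) / np.sqrt(len(totals))
        assert abs(mean - pre) < 3 * max(se, 1e-12)

    def test_invalid_target_rejected(self, rng):
        with pytest.raises(ValueError):
            resample(self._walkers([1.0]), target=0, rng=rng)
        with pytest.raises(ValueError):
            resample([], target=2, rng=rng)


class TestRunWe:
    @pytest.fixture
    def toy_setup(self):
        pot = double_well(barrier=3.0)
        prop = OverdampedLangevin(pot, dt=0.01)
        pts, _ = biased_seed_ensemble(pot, "basin_A_only", 200, seed=5)
        grid = extend_grid(build_grid(pts, n_bins=10), n_pad=5)
        return pot, prop, pts, grid

    def test_frozen_propagator_keeps_projections(self, toy_setup):
        _, _, pts, grid = toy_setup
        states = [pts[i] for i in range(10)]
        w = np.full(10, 0.1)
        hist = run_we(states, w, FrozenPropagator(), grid,
                      WEConfig(tau=1.0, target_per_bin=8, n_iterations=1, seed=0))
        rec = hist.iterations[0]
        np.testing.assert_array_equal(rec.start_proj, rec.end_proj)

    def test_weight_conservation(self, toy_setup):
        _, prop, pts, grid = toy_setup
        states = [pts[i] for i in range(20)]
        w = np.full(20, 0.05)
        hist = run_we(states, w, prop, grid,
                      WEConfig(tau=0.2, target_per_bin=4, n_iterations=25, seed=1))
        for rec in hist.iterations:
            assert abs(math.fsum(rec.weights) - 1.0) < 1e-12
        assert abs(math.fsum(w.weight for w in hist.final_walkers) - 1.0) < 1e-12

    def test_exploration_fills_bins(self, toy_setup):
        """From a one-basin seed, the number of occupied bins should grow
        during the early iterations as walkers spread."""
        _, prop, pts, grid = toy_setup
        from ensrect.grid_downsample import assign_bins

        states = [pts[i] for i in range(10)]
        w = np.full(10, 0.1)
        hist = run_we(states, w, prop, grid,
                      WEConfig(tau=0.5, target_per_bin=8, n_iterations=30, seed=2))
        occ = [
            len({tuple(b) for b in assign_bins(rec.end_proj, grid)})
            for rec in hist.iterations
        ]
        assert occ[-1] > occ[0]

    def test_single_walker_single_bin_is_plain_trajectory(self):
        """target=1 on a one-bin grid reduces WE to unbiased propagation."""
        pot = HarmonicWell(k=1.0)
        prop = OverdampedLangevin(pot, dt=0.01)
        grid = GridSpec(edges=[np.array([-100.0, 100.0])], n_core_bins=[1])
        x0 = np.array([1.5])
        cfg = WEConfig(tau=0.3, target_per_bin=1, n_iterations=10, seed=9)
        hist = run_we([x0], np.array([1.0]), prop, grid, cfg)
        # oracle: plain propagation with the identical per-iteration streams
        x = x0
        for it, rec in enumerate(hist.iterations):
            assert rec.weights[0] == pytest.approx(1.0, abs=1e-15)
            np.testing.assert_allclose(rec.start_proj[0], x)
            x = prop.propagate(x, cfg.tau, _walker_rng(cfg.seed, it, 0))
            np.testing.assert_allclose(rec.end_proj[0], x)

    def test_parent_ids_resolve(self, toy_setup):
        _, prop, pts, grid = toy_setup
        states = [pts[i] for i in range(10)]
        hist = run_we(states, np.full(10, 0.1), prop, grid,
                      WEConfig(tau=0.2, target_per_bin=3, n_iterations=5, seed=3))
        for prev, rec in zip(hist.iterations, hist.iterations[1:]):
            assert np.all(rec.parent_ids >= 0)
            assert np.all(rec.parent_ids < prev.n_walkers)

    def test_bad_initial_weights_rejected(self, toy_setup):
        _, prop, pts, grid = toy_setup
        with pytest.raises(ValueError):
            run_we([pts[0]], np.array([0.5]), prop, grid,
                   WEConfig(tau=0.1, n_iterations=1, seed=0))

    def test_propagator_failure_reports_iteration(self, toy_setup):
        _, _, pts, grid = toy_setup

        class Exploder:
            def propagate(self, state, tau, rng):
                raise FloatingPointError("boom")

            def project(self, state):
                return np.asarray(state)

        with pytest.raises(RuntimeError, match="iteration 0"):
            run_we([pts[0]], np.array([1.0]), Exploder(), grid,
                   WEConfig(tau=0.1, n_iterations=1, seed=0))


class TestHarmonicThermodynamics:
    def test_weighted_variance_matches_equipartition(self):
        """Long-run WE-weighted position variance on a harmonic well is kT/k."""
        k = 2.0
        pot = HarmonicWell(k=k)
        prop = OverdampedLangevin(pot, dt=0.005)
        grid = GridSpec(edges=[np.linspace(-3.0, 3.0, 13)], n_core_bins=[12])
        rng = np.random.default_rng(0)
        states = [np.array([x]) for x in rng.normal(0, 1.0, 16)]
        w = np.full(16, 1 / 16)
        cfg = WEConfig(tau=0.25, target_per_bin=4, n_iterations=400, seed=4)
        hist = run_we(states, w, prop, grid, cfg)
        # discard burn-in, then block-average the per-iteration weighted variance
        per_iter = np.array([
            np.sum(rec.weights * rec.end_proj[:, 0] ** 2) / np.sum(rec.weights)
            for rec in hist.iterations[100:]
        ])
        blocks = per_iter.reshape(20, -1).mean(axis=1)
        mean = blocks.mean()
        se = blocks.std(ddof=1) / np.sqrt(len(blocks))
        assert abs(mean - 1.0 / k) < 3 * se + 0.01 / k  # small O(dt) integrator bias


class TestHistoryArchive:
    def test_hdf5_roundtrip(self, tmp_path):
        pot = double_well(3.0)
        prop = OverdampedLangevin(pot, dt=0.01)
        pts, _ = biased_seed_ensemble(pot, "bimodal_50_50", 50, seed=8)
        grid = extend_grid(build_grid(pts, n_bins=5), n_pad=2)
        hist = run_we([pts[i] for i in range(8)], np.full(8, 1 / 8), prop, grid,
                      WEConfig(tau=0.2, target_per_bin=2, n_iterations=4, seed=6))
        path = tmp_path / "hist.h5"
        hist.save(path)
        back = WEHistory.load(path)
        assert len(back) == len(hist)
        for a, b in zip(back.iterations, hist.iterations):
            np.testing.assert_array_equal(a.weights, b.weights)
            np.testing.assert_array_equal(a.end_proj, b.end_proj)
            np.testing.assert_array_equal(a.parent_ids, b.parent_ids)
        assert back.config.tau == hist.config.tau
        assert back.grid.total_bins == hist.grid.total_bins
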