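"""Weighted-ensemble (WE) simulation with a pluggable dynamics propagator.

Many weighted trajectory copies ("walkers") are propagated for a resampling
interval τ, binned on an extended PC-space grid, and split/merged within each
bin toward a target count.  Splitting and merging conserve probability weight
exactly and are statistically unbiased, so the walker swarm samples the
propagator's true dynamics while keeping rare regions populated.

The propagator contract is minimal — ``propagate(state, tau, rng)`` and
``project(state)`` — so a molecular-dynamics engine can stand behind it.  A
bundled overdamped-Langevin integrator on analytic potentials serves as the
reference dynamics with known Boltzmann ground truth (dimensionless units,
kT = 1).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import h5py
import numpy as np

from .grid_downsample import GridSpec, assign_bins

__all__ = [
    "Walker",
    "WEConfig",
    "WEHistory",
    "IterationRecord",
    "Propagator",
    "OverdampedLangevin",
    "FrozenPropagator",
    "extend_grid",
    "resample",
    "run_we",
]


class Propagator(Protocol):
    """Dynamics engine contract: stateless between calls except via ``rng``."""

    def propagate(self, state, tau: float, rng: np.random.Generator): ...

    def project(self, state) -> np.ndarray: ...


@dataclass
class Walker:
    state: object
    weight: float
    parent_id: int
    walker_id: int

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("walker weight must be positive")


@dataclass
class WEConfig:
    tau: float
    target_per_bin: int = 8
    n_iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.target_per_bin < 1:
            raise ValueError("target_per_bin must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class IterationRecord:
    """Per-iteration segment table: one row per walker propagated this iteration."""

    walker_ids: np.ndarray
    parent_ids: np.ndarray
    start_proj: np.ndarray
    end_proj: np.ndarray
    weights: np.ndarray

    @property
    def n_walkers(self) -> int:
        return len(self.weights)


@dataclass
class WEHistory:
    """All iteration records plus the grid and configuration that produced them."""

    iterations: list[IterationRecord]
    grid: GridSpec
    config: WEConfig
    final_walkers: list[Walker] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.iterations)

    def total_segments(self) -> int:
        return sum(r.n_walkers for r in self.iterations)

    def save(self, path) -> None:
        """Persist as a hierarchical HDF5 archive: one group per iteration."""
        with h5py.File(path, "w") as f:
            f.attrs["grid"] = json.dumps(self.grid.to_dict())
            f.attrs["tau"] = self.config.tau
            f.attrs["target_per_bin"] = self.config.target_per_bin
            f.attrs["n_iterations"] = self.config.n_iterations
            f.attrs["seed"] = self.config.seed
            for i, rec in enumerate(self.iterations):
                g = f.create_group(f"iterations/{i:06d}")
                g.create_dataset("walker_id", data=rec.walker_ids)
                g.create_dataset("parent_id", data=rec.parent_ids)
                g.create_dataset("start_proj", data=rec.start_proj)
                g.create_dataset("end_proj", data=rec.end_proj)
                g.create_dataset("weight", data=rec.weights)

    @classmethod
    def load(cls, path) -> "WEHistory":
        with h5py.File(path, "r") as f:
            grid = GridSpec.from_dict(json.loads(f.attrs["grid"]))
            config = WEConfig(
                tau=float(f.attrs["tau"]),
                target_per_bin=int(f.attrs["target_per_bin"]),
                n_iterations=int(f.attrs["n_iterations"]),
                seed=int(f.attrs["seed"]),
            )
            iterations = []
            for key in sorted(f["iterations"]):
                g = f["iterations"][key]
                iterations.append(
                    IterationRecord(
                        walker_ids=g["walker_id"][...],
                        parent_ids=g["parent_id"][...],
                        start_proj=g["start_proj"][...],
                        end_proj=g["end_proj"][...],
                        weights=g["weight"][...],
                    )
                )
        return cls(iterations=iterations, grid=grid, config=config)


def extend_grid(grid: GridSpec, n_pad: int = 5) -> GridSpec:
    """Append ``n_pad`` core-width bins to each end of every dimension."""
    if n_pad < 0:
        raise ValueError("n_pad must be >= 0")
    if n_pad == 0:
        return GridSpec(
            edges=[e.copy() for e in grid.edges],
            n_core_bins=list(grid.n_core_bins),
            n_pad_bins=grid.n_pad_bins,
        )
    new_edges = []
    for e in grid.edges:
        w = e[1] - e[0]
        lo = e[0] - w * np.arange(n_pad, 0, -1)
        hi = e[-1] + w * np.arange(1, n_pad + 1)
        new_edges.append(np.concatenate([lo, e, hi]))
    return GridSpec(
        edges=new_edges,
        n_core_bins=list(grid.n_core_bins),
        n_pad_bins=grid.n_pad_bins + n_pad,
    )


def resample(
    walkers: Sequence[Walker], target: int, rng: np.random.Generator
) -> list[Walker]:
    """Split/merge the walkers of one bin to exactly ``target``, conserving weight.

    Splitting repeatedly halves the largest-weight walker; merging repeatedly
    combines the two smallest-weight walkers, the survivor's state chosen with
    probability proportional to weight.  Both operations are statistically
    unbiased and conserve the bin's total weight exactly.
    """
    if target < 1:
        raise ValueError("target must be >= 1")
    if not walkers:
        raise ValueError("cannot resample an empty bin")
    pool = [Walker(w.state, w.weight, w.parent_id, w.walker_id) for w in walkers]
    while len(pool) < target:
        i = max(range(len(pool)), key=lambda j: pool[j].weight)
        w = pool[i]
        half = w.weight / 2.0
        pool[i] = Walker(w.state, half, w.parent_id, w.walker_id)
        pool.append(Walker(w.state, w.weight - half, w.parent_id, w.walker_id))
    while len(pool) > target:
        order = sorted(range(len(pool)), key=lambda j: (pool[j].weight, j))
        i, j = order[0], order[1]
        a, b = pool[i], pool[j]
        total = a.weight + b.weight
        survivor = a if rng.random() < a.weight / total else b
        merged = Walker(survivor.state, total, survivor.parent_id, survivor.walker_id)
        for k in sorted((i, j), reverse=True):
            pool.pop(k)
        pool.append(merged)
    return pool


def _walker_rng(seed: int, iteration: int, walker_id: int) -> np.random.Generator:
    # Stream depends only on (seed, iteration, walker id): reproducible
    # regardless of execution order.
    return np.random.default_rng(np.random.SeedSequence([seed, iteration, walker_id]))


def _resample_rng(seed: int, iteration: int, flat_bin: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, iteration, 0x5E5A, flat_bin])
    )


def run_we(
    initial_states: Sequence,
    initial_weights: np.ndarray,
    propagator: Propagator,
    grid: GridSpec,
    config: WEConfig,
) -> WEHistory:
    """Run a weighted-ensemble simulation.

    Each iteration: propagate every walker for τ, record the segment
    (parentage, start/end projections, weight), bin end-point projections on
    the (extended) grid, and resample each occupied bin to
    ``config.target_per_bin`` walkers.  Total weight is renormalized against
    compensated summation each iteration, holding drift below 1e-12.
    """
    initial_weights = np.asarray(initial_weights, dtype=float)
    if len(initial_states) != len(initial_weights):
        raise ValueError("initial states and weights must align")
    if abs(math.fsum(initial_weights) - 1.0) > 1e-9:
        raise ValueError("initial weights must sum to 1")

    walkers = [
        Walker(state=s, weight=float(w), parent_id=-1, walker_id=i)
        for i, (s, w) in enumerate(zip(initial_states, initial_weights))
    ]
    iterations: list[IterationRecord] = []
    nb = grid.n_bins

    for it in range(config.n_iterations):
        n = len(walkers)
        start_proj = np.empty((n, grid.ndim))
        end_proj = np.empty((n, grid.ndim))
        new_states = []
        for w in walkers:
            start_proj[w.walker_id] = np.asarray(propagator.project(w.state))[: grid.ndim]
        rngs = [_walker_rng(config.seed, it, w.walker_id) for w in walkers]
        try:
            if hasattr(propagator, "propagate_batch"):
                new_states = propagator.propagate_batch(
                    [w.state for w in walkers], config.tau, rngs
                )
            else:
                new_states = [
                    propagator.propagate(w.state, config.tau, rng)
                    for w, rng in zip(walkers, rngs)
                ]
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise RuntimeError(f"propagator failed at iteration {it}") from exc
        for w, s_new in zip(walkers, new_states):
            end_proj[w.walker_id] = np.asarray(propagator.project(s_new))[: grid.ndim]
        iterations.append(
            IterationRecord(
                walker_ids=np.array([w.walker_id for w in walkers]),
                parent_ids=np.array([w.parent_id for w in walkers]),
                start_proj=start_proj.copy(),
                end_proj=end_proj.copy(),
                weights=np.array([w.weight for w in walkers]),
            )
        )
        # Bin on end-point projections; out-of-grid walkers clamp to edge bins.
        bin_idx = assign_bins(end_proj, grid)
        flat = np.ravel_multi_index(bin_idx.T, nb)
        groups: dict[int, list[Walker]] = {}
        for w, s_new, fb in zip(walkers, new_states, flat):
            child = Walker(state=s_new, weight=w.weight, parent_id=w.walker_id, walker_id=-1)
            groups.setdefault(int(fb), []).append(child)
        next_walkers: list[Walker] = []
        for fb in sorted(groups):
            rng = _resample_rng(config.seed, it, fb)
            next_walkers.extend(resample(groups[fb], config.target_per_bin, rng))
        total = math.fsum(w.weight for w in next_walkers)
        for new_id, w in enumerate(next_walkers):
            w.walker_id = new_id
            w.weight = w.weight / total
        walkers = next_walkers

    return WEHistory(
        iterations=iterations, grid=grid, config=config, final_walkers=walkers
    )


# ---------------------------------------------------------------------------
# Bundled propagators


class OverdampedLangevin:
    """Euler–Maruyama overdamped Langevin dynamics on an analytic potential.

    dx = −∇E/γ dt + sqrt(2 kT dt / γ) η.  Dimensionless units, kT = 1 by
    default.  ``project`` is the identity on the state (toy systems live
    directly in PC-like coordinates).
    """

    def __init__(self, potential, dt: float = 0.01, friction: float = 1.0, kT: float = 1.0):
        if dt <= 0 or friction <= 0 or kT <= 0:
            raise ValueError("dt, friction and kT must be positive")
        self.potential = potential
        self.dt = dt
        self.friction = friction
        self.kT = kT

    def propagate(self, state, tau: float, rng: np.random.Generator):
        x = np.asarray(state, dtype=float).copy()
        n_steps = max(1, int(round(tau / self.dt)))
        mob = self.dt / self.friction
        sigma = math.sqrt(2.0 * self.kT * self.dt / self.friction)
        noise = rng.standard_normal((n_steps, x.size)).reshape(n_steps, *x.shape)
        for k in range(n_steps):
            x = x - mob * self.potential.gradient(x) + sigma * noise[k]
        return x

    def propagate_batch(self, states, tau: float, rngs):
        """Vectorized propagation of many walkers at once.

        Each walker's noise comes from its own rng stream, drawn exactly as
        in :meth:`propagate`, so batch and per-walker execution agree
        bit-for-bit.
        """
        x = np.asarray(states, dtype=float).copy()
        n_steps = max(1, int(round(tau / self.dt)))
        mob = self.dt / self.friction
        sigma = math.sqrt(2.0 * self.kT * self.dt / self.friction)
        noise = np.stack(
            [rng.standard_normal((n_steps, x.shape[1])) for rng in rngs], axis=1
        )
        for k in range(n_steps):
            x = x - mob * self.potential.gradient(x) + sigma * noise[k]
        return list(x)

    def project(self, state) -> np.ndarray:
        return np.asarray(state, dtype=float)


class FrozenPropagator:
    """Propagator that never moves: useful for bookkeeping checks."""

    def propagate(self, state, tau: float, rng: np.random.Generator):
        return state

    def project(self, state) -> np.ndarray:
        return np.asarray(state, dtype=float)
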