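"""Randomized iterative reweighting of trajectory segments to steady state.

Weighted-ensemble output is a cloud of trajectory segments — (start, end)
configuration pairs with probability weights.  Because the run is finite,
those weights are generally not stationary.  This module iterates toward a
self-consistent stationary distribution: each iteration draws a *fresh,
random* partition of configuration space (k-means with random centers),
estimates the cluster-level transition matrix under the current weights,
solves its stationary distribution, and rescales the segment weights so the
cluster masses match it.  Randomizing the partition across iterations
removes the bias any single discretization would impose — the procedure acts
like a nearly continuum Markov-state model.  A small convex smoothing toward
the cluster-average weight damps iteration noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

from .ensemble_geometry import PCSpace
from .we_engine import WEHistory

__all__ = [
    "TransitionSet",
    "RWConfig",
    "RWResult",
    "ReducibleChainError",
    "collect_transitions",
    "stationary_distribution",
    "rw_iterate",
    "rw_diagnostics",
]


class ReducibleChainError(ValueError):
    """The transition matrix has no unique stationary distribution.

    Typically means the sampled segments do not connect all regions of
    configuration space; more weighted-ensemble sampling is needed.
    """


@dataclass
class TransitionSet:
    """Trajectory segments in the retained-PC subspace.

    start/end: (n_segments, n_dims) projections; weights: probabilities
    summing to one.  Each segment spans one resampling interval τ.
    """

    start: np.ndarray
    end: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.start = np.atleast_2d(np.asarray(self.start, dtype=float))
        self.end = np.atleast_2d(np.asarray(self.end, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.start.shape != self.end.shape:
            raise ValueError("start and end shapes differ")
        if len(self.weights) != len(self.start):
            raise ValueError("weights must align 1:1 with segments")
        if np.any(self.weights <= 0):
            raise ValueError("segment weights must be positive")
        total = self.weights.sum()
        if abs(total - 1.0) > 1e-9:
            self.weights = self.weights / total

    @property
    def n_segments(self) -> int:
        return len(self.weights)

    @property
    def n_dims(self) -> int:
        return self.start.shape[1]


@dataclass
class RWConfig:
    n_clusters: int = 2
    n_iterations: int = 5000
    smoothing: float = 0.01
    seed: int = 0
    variance_cutoff: float = 0.85
    avg_window: int = 0          # >0: report weights averaged over the final window
    kmeans_steps: int = 10
    retry_cap: int = 100

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if not (0.0 <= self.smoothing <= 1.0):
            raise ValueError("smoothing must lie in [0, 1]")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class RWResult:
    final_weights: np.ndarray
    weight_trace: np.ndarray     # per-iteration L1 change of the weight vector
    converged: bool
    n_redraws: int = 0
    max_norm_error: float = 0.0  # worst per-iteration |sum(weights) - 1|


def collect_transitions(history: WEHistory, space: PCSpace | None = None) -> TransitionSet:
    """Build the segment set from a WE history.

    One segment per walker per iteration — its start and end projections and
    the weight it carried during that iteration.  If a PC space is given the
    projections are truncated to its retained components; weights are
    renormalized over all segments.
    """
    if len(history) == 0:
        raise ValueError("history contains no iterations")
    starts, ends, weights = [], [], []
    for rec in history.iterations:
        starts.append(rec.start_proj)
        ends.append(rec.end_proj)
        weights.append(rec.weights)
    start = np.concatenate(starts)
    end = np.concatenate(ends)
    w = np.concatenate(weights)
    if space is not None:
        k = min(space.n_retained, start.shape[1])
        start, end = start[:, :k], end[:, :k]
    return TransitionSet(start=start, end=end, weights=w / w.sum())


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution π of a row-stochastic matrix: πT = π.

    Solved via the dominant left eigenvector with nonnegativity projection.
    Raises :class:`ReducibleChainError` when the chain is not irreducible
    (no unique π).
    """
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(np.abs(T.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("rows must sum to 1")
    n_comp, _ = connected_components(T > 0, directed=True, connection="strong")
    if n_comp != 1:
        raise ReducibleChainError(
            "transition matrix is reducible: segments do not connect all "
            "clusters; extend the weighted-ensemble sampling"
        )
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.where(pi < 0, 0.0, pi) if pi.sum() >= 0 else np.where(-pi < 0, 0.0, -pi)
    s = pi.sum()
    if s <= 0:
        raise ReducibleChainError("degenerate stationary eigenvector")
    return pi / s


def _kmeans_partition(
    points: np.ndarray, k: int, rng: np.random.Generator, n_steps: int
):
    """Lightweight k-means: random centers from the data, fixed Lloyd steps.

    Randomization across calls is deliberate — each reweighting iteration
    must see a different partition.  Returns (labels, centers); clusters may
    come back empty (the caller re-draws).
    """
    n = len(points)
    centers = points[rng.choice(n, size=k, replace=False)].copy()
    labels = None
    for _ in range(n_steps):
        labels = _assign_to_centers(points, centers)
        counts = np.bincount(labels, minlength=k)
        for d in range(points.shape[1]):
            sums = np.bincount(labels, weights=points[:, d], minlength=k)
            nz = counts > 0
            centers[nz, d] = sums[nz] / counts[nz]
    return labels, centers


def _assign_to_centers(points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    # argmin of |p - c|^2 = argmin of (|c|^2 - 2 p·c); |p|^2 is constant in c
    scores = (centers**2).sum(axis=1)[None, :] - 2.0 * (points @ centers.T)
    return np.argmin(scores, axis=1)


def rw_iterate(transitions: TransitionSet, config: RWConfig) -> RWResult:
    """Iterate segment weights toward the self-consistent stationary state.

    Per iteration:
      a. cluster segment END points into ``n_clusters`` by randomized
         k-means; assign START points to the same centers;
      b. build the cluster transition matrix under the current weights,
         T_ij = Σ w(start in i, end in j) / Σ w(start in i);
      c. solve π = stationary_distribution(T);
      d. raw update — rescale the segments *starting* in cluster i by
         π_i / W_i (W_i = their current summed weight), preserving relative
         weights within the cluster;
      e. smoothing — new = (1−s)·raw + s·(start-cluster mean of raw);
      f. renormalize; record the L1 change.

    Rescaling by start cluster keeps the transition estimate invariant to
    the update itself (a per-row factor cancels in T), which makes the
    self-consistency iteration a stable contraction; rescaling by end
    cluster instead couples the update back into the next T estimate and
    diverges on slowly mixing systems.

    Degenerate clusterings (empty cluster, zero start-weight row, reducible
    T) are re-drawn up to ``config.retry_cap`` times per iteration.
    """
    w = transitions.weights.copy()
    k = config.n_clusters
    if len(np.unique(transitions.end, axis=0)) < k:
        raise ValueError("need at least n_clusters distinct end points")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x52575F]))
    trace = np.empty(config.n_iterations)
    n_redraws = 0
    norm_err = 0.0
    w_sum_window = None
    window_start = config.n_iterations - config.avg_window if config.avg_window else None

    for it in range(config.n_iterations):
        for attempt in range(config.retry_cap + 1):
            labels_end, centers = _kmeans_partition(
                transitions.end, k, rng, config.kmeans_steps
            )
            if len(np.unique(labels_end)) < k:
                n_redraws += 1
                continue
            labels_start = _assign_to_centers(transitions.start, centers)
            w_start = np.bincount(labels_start, weights=w, minlength=k)
            if np.any(w_start <= 0):
                n_redraws += 1
                continue
            flow = np.zeros((k, k))
            np.add.at(flow, (labels_start, labels_end), w)
            T = flow / w_start[:, None]
            try:
                pi = stationary_distribution(T)
            except ReducibleChainError:
                n_redraws += 1
                continue
            break
        else:
            raise ReducibleChainError(
                f"no usable clustering after {config.retry_cap} redraws at "
                f"iteration {it}; extend the weighted-ensemble sampling"
            )
        raw = w * (pi / w_start)[labels_start]
        if config.smoothing > 0.0:
            counts = np.bincount(labels_start, minlength=k)
            cluster_mean = np.bincount(labels_start, weights=raw, minlength=k) / counts
            new_w = (1.0 - config.smoothing) * raw + config.smoothing * cluster_mean[labels_start]
        else:
            new_w = raw
        new_w = new_w / new_w.sum()
        norm_err = max(norm_err, abs(float(new_w.sum()) - 1.0))
        trace[it] = np.abs(new_w - w).sum()
        w = new_w
        if window_start is not None and it >= window_start:
            w_sum_window = w.copy() if w_sum_window is None else w_sum_window + w

    if w_sum_window is not None:
        final = w_sum_window / w_sum_window.sum()
    else:
        final = w
    summary = rw_diagnostics_trace(trace, window=min(100, config.n_iterations))
    return RWResult(
        final_weights=final,
        weight_trace=trace,
        converged=summary["converged"],
        n_redraws=n_redraws,
        max_norm_error=norm_err,
    )


def rw_diagnostics_trace(trace: np.ndarray, window: int, tol: float = 1e-3) -> dict:
    """Sliding-window convergence summary of an L1-change trace."""
    trace = np.asarray(trace, dtype=float)
    if window > len(trace):
        raise ValueError("window exceeds the number of iterations")
    tail = trace[-window:]
    return {
        "window": int(window),
        "window_mean": float(tail.mean()),
        "window_max": float(tail.max()),
        "global_mean": float(trace.mean()),
        "converged": bool(tail.mean() < tol),
    }


def rw_diagnostics(result: RWResult, window: int, tol: float = 1e-3) -> dict:
    """Convergence summary of a reweighting run (window mean/max of L1 change)."""
    return rw_diagnostics_trace(result.weight_trace, window, tol)
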