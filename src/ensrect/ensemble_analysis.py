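"""Weighted distributions along principal components and ensemble comparison.

The end product of the pipeline is a probability distribution over a
collective coordinate (typically PC1).  This module bins weighted point sets
into mass histograms, averages the final iterations of a weighted-ensemble
run, and quantifies agreement between distributions with the Jensen–Shannon
divergence (natural log, so 0 ≤ JS ≤ ln 2 nats).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import rel_entr

from .we_engine import WEHistory

__all__ = [
    "WeightedHistogram",
    "weighted_histogram",
    "we_final_distribution",
    "js_divergence",
]


@dataclass
class WeightedHistogram:
    """Probability mass per bin (not density): sums to one."""

    edges: np.ndarray
    densities: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        if len(self.densities) != len(self.edges) - 1:
            raise ValueError("need exactly one mass per bin")
        if np.any(self.densities < 0):
            raise ValueError("bin masses must be non-negative")
        total = self.densities.sum()
        if total > 0 and abs(total - 1.0) > 1e-9:
            self.densities = self.densities / total

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("edge_lo,edge_hi,mass\n")
            for lo, hi, m in zip(self.edges[:-1], self.edges[1:], self.densities):
                fh.write(f"{lo:.10g},{hi:.10g},{m:.12g}\n")

    @classmethod
    def from_csv(cls, path, label: str = "") -> "WeightedHistogram":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        edges = np.append(data[:, 0], data[-1, 1])
        return cls(edges=edges, densities=data[:, 2], label=label)


def _bin_indices(points: np.ndarray, edges: np.ndarray) -> np.ndarray:
    # Half-open [lo, hi) bins, top bin closed, out-of-range clamps to edge bins
    # (identical convention to the downsampling grid).
    idx = np.searchsorted(edges, points, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def weighted_histogram(
    points: np.ndarray,
    weights: np.ndarray,
    edges: np.ndarray,
    label: str = "",
) -> WeightedHistogram:
    """Bin a weighted 1D point set into per-bin probability mass."""
    points = np.asarray(points, dtype=float).ravel()
    weights = np.asarray(weights, dtype=float).ravel()
    edges = np.asarray(edges, dtype=float)
    if len(points) != len(weights):
        raise ValueError(
            f"{len(points)} points but {len(weights)} weights"
        )
    idx = _bin_indices(points, edges)
    mass = np.bincount(idx, weights=weights, minlength=len(edges) - 1)
    return WeightedHistogram(edges=edges, densities=mass, label=label)


def we_final_distribution(
    history: WEHistory,
    n_final: int,
    edges: np.ndarray,
    dim: int = 0,
    label: str = "",
) -> WeightedHistogram:
    """Average the per-iteration end-point histograms over the final iterations."""
    if n_final < 1:
        raise ValueError("n_final must be >= 1")
    if len(history) < n_final:
        raise ValueError(
            f"history has {len(history)} iterations, fewer than n_final={n_final}"
        )
    acc = np.zeros(len(edges) - 1)
    for rec in history.iterations[-n_final:]:
        h = weighted_histogram(rec.end_proj[:, dim], rec.weights, edges)
        acc += h.densities
    return WeightedHistogram(edges=edges, densities=acc / n_final, label=label)


def js_divergence(p: WeightedHistogram, q: WeightedHistogram) -> float:
    """Jensen–Shannon divergence between two histograms, in nats.

    Requires identical edges.  Zero-mass bins contribute nothing
    (0·log 0 = 0); disjoint supports give ln 2.
    """
    if p.edges.shape != q.edges.shape or not np.allclose(p.edges, q.edges):
        raise ValueError("histograms must share identical edges")
    a, b = p.densities, q.densities
    m = 0.5 * (a + b)
    return float(0.5 * rel_entr(a, m).sum() + 0.5 * rel_entr(b, m).sum())
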