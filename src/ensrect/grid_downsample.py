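"""Rectilinear PC-space grid: downsampling bins and count-based weights.

A seed ensemble projected onto (PC1, PC2) is partitioned into equal-width
bins per dimension, spanning the rounded data range.  Downsampling keeps one
randomly chosen structure per occupied bin and hands it the bin's occupancy
fraction as its probability weight — the compact, weighted starting point
for weighted-ensemble relaxation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .structure_io import StructureEnsemble

__all__ = ["GridSpec", "build_grid", "assign_bin", "downsample"]

_EDGE_TOL = 1e-9


def _round_tenth(x: float) -> float:
    # round-half-away-from-zero to the nearest 0.1
    return float(np.sign(x) * np.floor(np.abs(x) * 10.0 + 0.5) / 10.0)


@dataclass
class GridSpec:
    """Per-dimension bin edges; core bins plus optional equal-width padding."""

    edges: list[np.ndarray]
    n_core_bins: list[int]
    n_pad_bins: int = 0

    def __post_init__(self) -> None:
        self.edges = [np.asarray(e, dtype=float) for e in self.edges]
        for d, e in enumerate(self.edges):
            if len(e) < 2 or np.any(np.diff(e) <= 0):
                raise ValueError(f"dimension {d}: edges must be strictly increasing")
            widths = np.diff(e)
            if np.any(np.abs(widths - widths[0]) > _EDGE_TOL * max(1.0, abs(widths[0]))):
                raise ValueError(f"dimension {d}: bins must be equal width")

    @property
    def ndim(self) -> int:
        return len(self.edges)

    @property
    def n_bins(self) -> list[int]:
        return [len(e) - 1 for e in self.edges]

    @property
    def total_bins(self) -> int:
        return int(np.prod(self.n_bins))

    def to_dict(self) -> dict:
        return {
            "edges": [e.tolist() for e in self.edges],
            "n_core_bins": list(self.n_core_bins),
            "n_pad_bins": int(self.n_pad_bins),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(
            edges=[np.asarray(e) for e in d["edges"]],
            n_core_bins=list(d["n_core_bins"]),
            n_pad_bins=int(d["n_pad_bins"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "GridSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_grid(projections: np.ndarray, n_bins: int = 10) -> GridSpec:
    """Equal-width grid over the projection range, rounded to the nearest tenth.

    Per dimension the lower (upper) edge is the data minimum (maximum)
    rounded to the nearest 0.1; if rounding collapses the range it is
    expanded by 0.1 on each side.  ``n_bins`` equal-width bins span it.
    """
    proj = np.atleast_2d(np.asarray(projections, dtype=float))
    if proj.size == 0:
        raise ValueError("no projections given")
    if not np.all(np.isfinite(proj)):
        raise ValueError("projections contain non-finite values")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    edges = []
    for d in range(proj.shape[1]):
        lo = _round_tenth(float(proj[:, d].min()))
        hi = _round_tenth(float(proj[:, d].max()))
        if hi - lo < 1e-12:
            lo, hi = lo - 0.1, hi + 0.1
        edges.append(np.linspace(lo, hi, n_bins + 1))
    return GridSpec(edges=edges, n_core_bins=[n_bins] * proj.shape[1])


def assign_bin(point: np.ndarray, grid: GridSpec) -> tuple[int, ...]:
    """Bin index per dimension: half-open [lo, hi), top bin closed, outliers clamped."""
    point = np.asarray(point, dtype=float)
    idx = []
    for d in range(grid.ndim):
        e = grid.edges[d]
        i = int(np.searchsorted(e, point[d], side="right") - 1)
        i = min(max(i, 0), len(e) - 2)
        idx.append(i)
    return tuple(idx)


def assign_bins(points: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Vectorized :func:`assign_bin` → (N, ndim) integer array."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.empty((pts.shape[0], grid.ndim), dtype=int)
    for d in range(grid.ndim):
        e = grid.edges[d]
        i = np.searchsorted(e, pts[:, d], side="right") - 1
        out[:, d] = np.clip(i, 0, len(e) - 2)
    return out


def downsample(
    ensemble: StructureEnsemble,
    projections: np.ndarray,
    grid: GridSpec,
    seed: int,
):
    """One member per occupied bin, weighted by the bin's occupancy fraction.

    Within each occupied bin one member is drawn uniformly at random (seeded);
    its weight is occupancy / total members, so weights sum to one exactly.
    Returns ``(downsampled_ensemble, records)`` where records is a list of
    (original_index, bin_index_tuple, weight) for the sidecar weight table.
    """
    proj = np.atleast_2d(np.asarray(projections, dtype=float))
    n = len(ensemble)
    if proj.shape[0] != n:
        raise ValueError("projections must align 1:1 with ensemble members")
    bins = assign_bins(proj, grid)
    groups: dict[tuple[int, ...], list[int]] = {}
    for i in range(n):
        groups.setdefault(tuple(bins[i]), []).append(i)
    rng = np.random.default_rng(seed)
    chosen, weights, records = [], [], []
    for b in sorted(groups):  # index-sorted bins → order-invariant selection
        members = groups[b]
        pick = members[rng.integers(len(members))]
        w = len(members) / n
        chosen.append(ensemble.members[pick])
        weights.append(w)
        records.append((pick, b, w))
    out = StructureEnsemble(
        members=chosen,
        weights=np.asarray(weights),
        source_label=ensemble.source_label + ":downsampled",
    )
    return out, records


def write_weight_table(records, path) -> None:
    """Sidecar weight table: original index, bin indices, weight."""
    with open(path, "w") as fh:
        fh.write("index\tbin\tweight\n")
        for idx, b, w in records:
            fh.write(f"{idx}\t{','.join(map(str, b))}\t{w:.12g}\n")
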