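"""Choose the joint alignment reference by density-based clustering.

The reference structure is the medoid of the dominant DBSCAN cluster of the
pairwise Cα-RMSD matrix.  The DBSCAN radius is read off the sorted
k-th-nearest-neighbour distance curve ("k-distance elbow"), scanned over a
range of k; among the candidate (eps, k) pairs the one whose clustering
leaves the largest fraction of members in the main cluster wins, ties going
to the smallest k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN

from .ensemble_geometry import kabsch_superpose
from .structure_io import StructureEnsemble

__all__ = [
    "DistanceMatrix",
    "ClusterLabels",
    "ClusterReport",
    "pairwise_rmsd",
    "kdistance_eps",
    "dbscan",
    "select_reference",
]


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise superposed Cα RMSDs (Å)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if np.any(v < 0) or np.any(np.diag(v) > 1e-12):
            raise ValueError("distances must be non-negative with zero diagonal")
        self.values = v

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class ClusterLabels:
    """DBSCAN labels (−1 = noise) plus the parameters that produced them."""

    labels: np.ndarray
    eps: float
    min_samples: int

    def cluster_sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels[self.labels >= 0], return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))


@dataclass
class ClusterReport:
    sizes: dict[int, int]
    n_noise: int
    medoid_index: int
    eps: float
    min_samples: int
    secondary_fraction: float
    secondary_exceeds_1pct: bool

    def to_table(self) -> str:
        """Tabular text summary: cluster id, size, fraction, medoid index."""
        total = sum(self.sizes.values()) + self.n_noise
        lines = ["cluster_id\tsize\tfraction\tmedoid_index"]
        largest = max(self.sizes, key=lambda c: (self.sizes[c], -c), default=-1)
        for cid in sorted(self.sizes):
            med = self.medoid_index if cid == largest else -1
            lines.append(f"{cid}\t{self.sizes[cid]}\t{self.sizes[cid]/total:.6f}\t{med}")
        if self.n_noise:
            lines.append(f"-1\t{self.n_noise}\t{self.n_noise/total:.6f}\t-1")
        return "\n".join(lines) + "\n"


def pairwise_rmsd(ensemble: StructureEnsemble) -> DistanceMatrix:
    """All-vs-all Kabsch-superposed Cα RMSD."""
    n = len(ensemble)
    if n < 2:
        raise ValueError("pairwise RMSD requires at least 2 members")
    coords = ensemble.coord_array()
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, r = kabsch_superpose(coords[j], coords[i])
            out[i, j] = out[j, i] = r
    return DistanceMatrix(out)


def _elbow(curve: np.ndarray) -> float:
    """Value at the point of maximum perpendicular distance to the endpoint chord."""
    n = len(curve)
    if n < 3 or curve[-1] - curve[0] < 1e-15:
        return float(curve[-1])
    x = np.arange(n, dtype=float)
    p0 = np.array([0.0, curve[0]])
    p1 = np.array([n - 1.0, curve[-1]])
    chord = p1 - p0
    chord /= np.linalg.norm(chord)
    rel = np.stack([x, curve], axis=1) - p0
    # perpendicular distance = |cross product| with the unit chord
    perp = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
    return float(curve[int(np.argmax(perp))])


def kdistance_eps(dm: DistanceMatrix, k_min: int = 2, k_max: int = 10):
    """Select (eps, k) by the k-distance elbow over k in [k_min, k_max].

    For each k the sorted k-th-nearest-neighbour distance curve yields an eps
    candidate at its elbow; the candidate whose DBSCAN run (min_samples = k)
    keeps the largest fraction of members in the main cluster is returned,
    ties broken toward smaller k.
    """
    n = len(dm)
    if n < k_max + 1:
        raise ValueError(f"need more than k_max={k_max} members, have {n}")
    sorted_rows = np.sort(dm.values, axis=1)  # column 0 is the zero self-distance
    best = None
    for k in range(k_min, k_max + 1):
        curve = np.sort(sorted_rows[:, k])
        eps = _elbow(curve)
        if eps <= 0:  # all candidate points coincide
            eps = max(float(sorted_rows[:, k].max()), 1e-12)
        labels = dbscan(dm, eps=eps, min_samples=k)
        sizes = labels.cluster_sizes()
        main_frac = max(sizes.values()) / n if sizes else 0.0
        if best is None or main_frac > best[0] + 1e-12:
            best = (main_frac, eps, k)
    return best[1], best[2]


def dbscan(dm: DistanceMatrix, eps: float, min_samples: int) -> ClusterLabels:
    """Density-based clustering on the precomputed distance matrix."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    model = DBSCAN(eps=eps, min_samples=min_samples, metric="precomputed")
    labels = model.fit_predict(dm.values)
    return ClusterLabels(labels=labels, eps=float(eps), min_samples=int(min_samples))


def _medoid(dm_values: np.ndarray, indices: np.ndarray) -> int:
    sub = dm_values[np.ix_(indices, indices)]
    return int(indices[int(np.argmin(sub.sum(axis=1)))])  # argmin takes lowest index on ties


def select_reference(ensemble: StructureEnsemble, k_min: int = 2, k_max: int = 10):
    """Pick the alignment reference: medoid of the largest DBSCAN cluster.

    Returns ``(reference_coords, report)``.  If every member is labelled
    noise the global medoid is used and a warning is emitted.  The report
    flags when secondary clusters hold more than 1% of the dataset.
    """
    n = len(ensemble)
    if n < 2:
        raise ValueError("reference selection requires at least 2 members")
    dm = pairwise_rmsd(ensemble)
    k_max_eff = min(k_max, n - 1)
    k_min_eff = min(k_min, k_max_eff)
    eps, k = kdistance_eps(dm, k_min_eff, k_max_eff)
    labels = dbscan(dm, eps=eps, min_samples=k)
    sizes = labels.cluster_sizes()
    if not sizes:
        warnings.warn("all members labelled noise; falling back to global medoid")
        medoid = _medoid(dm.values, np.arange(n))
        report = ClusterReport(
            sizes={}, n_noise=n, medoid_index=medoid, eps=eps, min_samples=k,
            secondary_fraction=0.0, secondary_exceeds_1pct=False,
        )
        return ensemble.members[medoid].coords, report
    largest = max(sizes, key=lambda c: (sizes[c], -c))
    members_in = np.flatnonzero(labels.labels == largest)
    medoid = _medoid(dm.values, members_in)
    secondary = sum(s for c, s in sizes.items() if c != largest)
    frac = secondary / n
    report = ClusterReport(
        sizes=sizes,
        n_noise=int(np.sum(labels.labels == -1)),
        medoid_index=medoid,
        eps=eps,
        min_samples=k,
        secondary_fraction=frac,
        secondary_exceeds_1pct=frac > 0.01,
    )
    return ensemble.members[medoid].coords, report
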