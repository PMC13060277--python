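"""Synthetic systems with known ground truth.

Real inputs to the pipeline — AI-generated protein ensembles relaxed by
molecular dynamics — are expensive and have no analytic reference.  The
generators here reproduce their essential features at desk scale:

* 2D analytic potentials (double well) whose Boltzmann distribution is
  computable by quadrature, standing in for the open/closed conformational
  landscape of a protein;
* biased point ensembles on those potentials, mimicking structure
  generators that oversample one basin or split between basins;
* discrete Markov-chain transition fixtures with an analytic stationary
  vector, for validating the reweighting solver;
* small protein-like Cα ensembles with planted deformation modes, for
  exercising alignment, PCA, clustering and downsampling.

Everything is deterministic under a fixed seed; dimensionless units with
kT = 1 throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .riteweight import TransitionSet
from .structure_io import Structure, StructureEnsemble

__all__ = [
    "ToyPotential",
    "SyntheticSpec",
    "double_well",
    "boltzmann_quadrature",
    "biased_seed_ensemble",
    "markov_chain_transitions",
    "synthetic_ca_ensemble",
]


@dataclass
class ToyPotential:
    """Analytic 2D potential: energy, gradient and rectangular domain bounds."""

    energy_fn: callable
    gradient_fn: callable
    bounds: np.ndarray  # (2, 2): [[x_lo, x_hi], [y_lo, y_hi]]
    saddle_x: float = 0.0

    def energy(self, point) -> float | np.ndarray:
        return self.energy_fn(np.asarray(point, dtype=float))

    def gradient(self, point) -> np.ndarray:
        return self.gradient_fn(np.asarray(point, dtype=float))


@dataclass
class SyntheticSpec:
    """Recipe for a protein-like Cα ensemble with planted deformation modes."""

    mode_amplitudes: tuple = (1.0,)
    noise_scale: float = 0.0
    n_members: int = 10
    n_residues: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 2:
            raise ValueError("n_members must be >= 2")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")


def double_well(
    barrier: float = 3.0,
    separation: float = 2.0,
    transverse_stiffness: float = 1.0,
    asymmetry: float = 0.0,
) -> ToyPotential:
    """Quartic double well along x, harmonic along y (kT = 1 units).

    E(x, y) = barrier·((x/a)² − 1)² + ½·k_y·y² + ΔE·σ(x), a = separation/2,
    where σ is a smooth unit step centred on the saddle (width a/12) so a
    nonzero ``asymmetry`` ΔE raises basin B (x > 0) by ΔE without reshaping
    either basin.  Minima near x = ±a; saddle at x = 0 with energy
    ``barrier`` above the lower basin.
    """
    if barrier <= 0:
        raise ValueError("barrier must be positive")
    a = separation / 2.0
    ky = transverse_stiffness
    w = a / 12.0  # narrow enough that the step is flat at both minima

    def energy(p):
        p = np.asarray(p, dtype=float)
        x, y = p[..., 0], p[..., 1]
        e = barrier * ((x / a) ** 2 - 1.0) ** 2 + 0.5 * ky * y**2
        if asymmetry != 0.0:
            e = e + asymmetry * 0.5 * (1.0 + np.tanh(x / w))
        return e

    def gradient(p):
        p = np.asarray(p, dtype=float)
        x, y = p[..., 0], p[..., 1]
        gx = 4.0 * barrier * x * ((x / a) ** 2 - 1.0) / a**2
        if asymmetry != 0.0:
            gx = gx + asymmetry * 0.5 / (w * np.cosh(x / w) ** 2)
        gy = ky * y
        return np.stack([gx, gy], axis=-1)

    half_x = a + max(2.5, 3.0 / math.sqrt(8.0 * barrier / a**2))
    half_y = max(2.5, 4.0 / math.sqrt(ky))
    bounds = np.array([[-half_x, half_x], [-half_y, half_y]])
    return ToyPotential(energy_fn=energy, gradient_fn=gradient, bounds=bounds)


def boltzmann_quadrature(potential: ToyPotential, n_grid: int = 400):
    """Boltzmann density on a trapezoidal quadrature grid at kT = 1.

    Returns ``(x, y, density)`` with density normalized to integrate to one
    over the potential's domain bounds.
    """
    (x0, x1), (y0, y1) = potential.bounds
    x = np.linspace(x0, x1, n_grid)
    y = np.linspace(y0, y1, n_grid)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    e = potential.energy(np.stack([xx, yy], axis=-1))
    p = np.exp(-(e - e.min()))
    z = np.trapezoid(np.trapezoid(p, y, axis=1), x)
    return x, y, p / z


def boltzmann_marginal_histogram(potential: ToyPotential, edges: np.ndarray, n_grid: int = 400):
    """Quadrature Boltzmann mass per bin along x, on the given edges."""
    x, y, dens = boltzmann_quadrature(potential, n_grid)
    marg = np.trapezoid(dens, y, axis=1)
    mass = np.empty(len(edges) - 1)
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        # clamp convention: edge bins absorb out-of-range mass
        lo_i = -np.inf if i == 0 else lo
        hi_i = np.inf if i == len(edges) - 2 else hi
        mask = (x >= lo_i) & (x < hi_i)
        mass[i] = np.trapezoid(np.where(mask, marg, 0.0), x)
    return mass / mass.sum()


def basin_populations(potential: ToyPotential, n_grid: int = 400):
    """Quadrature basin populations (P_A, P_B), split at the saddle."""
    x, y, dens = boltzmann_quadrature(potential, n_grid)
    marg = np.trapezoid(dens, y, axis=1)
    left = x < potential.saddle_x
    pa = np.trapezoid(np.where(left, marg, 0.0), x)
    pb = np.trapezoid(np.where(~left, marg, 0.0), x)
    total = pa + pb
    return pa / total, pb / total


_STYLES = ("basin_A_only", "basin_B_only", "bimodal_50_50")


def biased_seed_ensemble(
    potential: ToyPotential,
    style: str,
    n: int,
    seed: int,
    max_tries: int = 10_000_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample a biased point ensemble on the potential.

    ``basin_A_only`` restricts to x below the saddle, ``basin_B_only`` above,
    ``bimodal_50_50`` draws half from each basin.  Within the allowed region
    points follow the Boltzmann density at kT = 1.  Returns (points (n, 2),
    uniform weights).
    """
    if style not in _STYLES:
        raise ValueError(f"style must be one of {_STYLES}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    (x0, x1), (y0, y1) = potential.bounds
    sx = potential.saddle_x

    def draw(n_want, x_lo, x_hi):
        out = np.empty((n_want, 2))
        got, tries = 0, 0
        # acceptance envelope: exp(-(E - global_min)) <= 1
        probe = np.linspace(x_lo, x_hi, 200)
        e_min = float(
            potential.energy(np.stack([probe, np.zeros_like(probe)], axis=-1)).min()
        )
        while got < n_want:
            batch = max(256, 2 * (n_want - got))
            tries += batch
            if tries > max_tries:
                raise RuntimeError("rejection sampling failed to converge")
            cand = np.column_stack(
                [rng.uniform(x_lo, x_hi, batch), rng.uniform(y0, y1, batch)]
            )
            acc = rng.random(batch) < np.exp(-(potential.energy(cand) - e_min))
            take = cand[acc][: n_want - got]
            out[got : got + len(take)] = take
            got += len(take)
        return out

    if style == "basin_A_only":
        pts = draw(n, x0, sx)
    elif style == "basin_B_only":
        pts = draw(n, sx, x1)
    else:
        n_a = n // 2
        pts = np.concatenate([draw(n_a, x0, sx), draw(n - n_a, sx, x1)])
    return pts, np.full(n, 1.0 / n)


def markov_chain_transitions(
    T: np.ndarray,
    state_centers: np.ndarray,
    n_segments: int,
    initial_weights: np.ndarray,
    seed: int,
    jitter: float = 0.05,
) -> TransitionSet:
    """Segment fixture from a discrete Markov chain with known stationary vector.

    Segment start states are allocated deterministically in proportion to
    ``initial_weights`` (largest-remainder rounding), with per-segment weight
    initial_weights[i]/n_i so the aggregated start-state mass reproduces
    ``initial_weights`` exactly.  End states are drawn from the matching row
    of ``T``.  Points are the state centers plus Gaussian jitter.
    """
    T = np.asarray(T, dtype=float)
    centers = np.atleast_2d(np.asarray(state_centers, dtype=float))
    k = T.shape[0]
    if T.shape != (k, k) or np.any(np.abs(T.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("T must be square and row-stochastic")
    if len(centers) != k:
        raise ValueError("one center per state required")
    w0 = np.asarray(initial_weights, dtype=float)
    w0 = w0 / w0.sum()
    rng = np.random.default_rng(seed)

    quota = w0 * n_segments
    counts = np.floor(quota).astype(int)
    rem = n_segments - counts.sum()
    order = np.argsort(-(quota - counts))
    counts[order[:rem]] += 1
    if np.any((counts == 0) & (w0 > 0)):
        raise ValueError("n_segments too small to represent initial_weights")

    starts, ends, weights = [], [], []
    for i in range(k):
        if counts[i] == 0:
            continue
        end_states = rng.choice(k, size=counts[i], p=T[i])
        starts.append(np.full(counts[i], i))
        ends.append(end_states)
        weights.append(np.full(counts[i], w0[i] / counts[i]))
    start_states = np.concatenate(starts)
    end_states = np.concatenate(ends)
    w = np.concatenate(weights)
    d = centers.shape[1]
    start_pts = centers[start_states] + jitter * rng.standard_normal((len(w), d))
    end_pts = centers[end_states] + jitter * rng.standard_normal((len(w), d))
    return TransitionSet(start=start_pts, end=end_pts, weights=w)


def _base_helix(n_residues: int) -> np.ndarray:
    # idealized Cα helix: rise 1.5 Å, radius 2.3 Å, 100° per residue
    t = np.arange(n_residues) * np.deg2rad(100.0)
    return np.column_stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n_residues)])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def synthetic_ca_ensemble(spec: SyntheticSpec) -> tuple[StructureEnsemble, np.ndarray]:
    """Protein-like Cα ensemble with planted orthogonal deformation modes.

    Members are the base helix deformed along ``len(mode_amplitudes)``
    random orthonormal 3M-dimensional modes with standard-normal amplitudes
    scaled by ``mode_amplitudes``, plus isotropic noise, then randomly
    rotated and translated (alignment is nontrivial).  Returns
    ``(ensemble, mode_coefficients)`` where mode_coefficients[(i, k)] is the
    amplitude of mode k in member i — the bookkeeping for PCA validation.
    """
    rng = np.random.default_rng(spec.seed)
    base = _base_helix(spec.n_residues)
    dim = base.size
    n_modes = len(spec.mode_amplitudes)
    raw = rng.standard_normal((dim, n_modes))
    modes, _ = np.linalg.qr(raw)  # orthonormal columns
    coeffs = rng.standard_normal((spec.n_members, n_modes)) * np.asarray(
        spec.mode_amplitudes
    )
    members = []
    for i in range(spec.n_members):
        flat = base.ravel() + modes @ coeffs[i]
        coords = flat.reshape(-1, 3)
        if spec.noise_scale > 0:
            coords = coords + spec.noise_scale * rng.standard_normal(coords.shape)
        rot = _random_rotation(rng)
        shift = rng.uniform(-20.0, 20.0, 3)
        coords = coords @ rot.T + shift
        members.append(
            Structure(
                atom_names=["CA"] * spec.n_residues,
                residue_ids=list(range(1, spec.n_residues + 1)),
                coords=coords,
                model_id=i + 1,
            )
        )
    return (
        StructureEnsemble(members=members, source_label=f"synthetic(seed={spec.seed})"),
        coeffs,
    )
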