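"""Pipeline configuration and stage orchestration.

Three stages rectify an arbitrary conformational ensemble toward the
equilibrium of a given dynamics engine:

1. *preprocess* — pick a joint alignment reference (DBSCAN medoid), align,
   fit the joint PC space;
2. *downsample* — grid the (PC1, PC2) projection, keep one structure per
   occupied bin with count weights;
3. *run-we* + *riteweight* — weighted-ensemble relaxation from the
   downsampled seeds, then randomized iterative reweighting of the WE
   segments to the self-consistent stationary distribution.

`run_toy_demo` wires the full pipeline on a 2D double-well potential with
three deliberately dissimilar seed ensembles, the desk-scale analogue of
feeding dissimilar AI-generated protein ensembles into the same machinery.
The defaults mirror the reference protocol: 10 core bins per PC, 5 pad bins
per end (400 WE bins), 8 walkers per bin, 2 reweighting clusters, 1%
smoothing, 85% variance cutoff.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .ensemble_analysis import (
    WeightedHistogram,
    js_divergence,
    weighted_histogram,
    we_final_distribution,
)
from .ensemble_geometry import align_ensemble, fit_pca, project
from .grid_downsample import GridSpec, assign_bins, build_grid, downsample
from .reference_selection import select_reference
from .riteweight import RWConfig, collect_transitions, rw_iterate
from .structure_io import StructureEnsemble
from .synthetic_systems import (
    biased_seed_ensemble,
    boltzmann_marginal_histogram,
    double_well,
)
from .we_engine import OverdampedLangevin, WEConfig, WEHistory, extend_grid, run_we

__all__ = ["PipelineConfig", "ConfigError", "run_toy_demo", "DemoResult"]


class ConfigError(ValueError):
    """A configuration value violates a stage precondition."""


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the reference protocol settings."""

    n_bins: int = 10
    n_pad: int = 5
    target_per_bin: int = 8
    tau: float = 0.5
    we_iterations: int = 200
    variance_cutoff: float = 0.85
    n_clusters: int = 2
    rw_iterations: int = 5000
    smoothing: float = 0.01
    seed: int = 0
    # toy-propagator parameters (dimensionless, kT = 1)
    dt: float = 0.01
    friction: float = 1.0
    kT: float = 1.0
    barrier: float = 3.0
    n_seed_points: int = 2000
    rw_avg_window: int = 100

    def __post_init__(self) -> None:
        checks = [
            (self.n_bins >= 1, "n_bins must be >= 1"),
            (self.n_pad >= 0, "n_pad must be >= 0"),
            (self.target_per_bin >= 1, "target_per_bin must be >= 1"),
            (self.tau > 0, "tau must be positive"),
            (self.we_iterations >= 1, "we_iterations must be >= 1"),
            (0 < self.variance_cutoff <= 1, "variance_cutoff must be in (0, 1]"),
            (self.n_clusters >= 2, "n_clusters must be >= 2"),
            (self.rw_iterations >= 1, "rw_iterations must be >= 1"),
            (0 <= self.smoothing <= 1, "smoothing must lie in [0, 1]"),
            (self.dt > 0, "dt must be positive"),
            (self.friction > 0, "friction must be positive"),
            (self.kT > 0, "kT must be positive"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Parse a key = value text config; unknown keys are rejected."""
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
            default = getattr(cls, key, None)
            caster = int if isinstance(default, int) else float
            kwargs[key] = caster(value)
        return cls(**kwargs)

    def to_file(self, path) -> None:
        lines = [
            f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def provenance_record(config: PipelineConfig, stage: str, inputs=()) -> dict:
    """Structured provenance entry: config hash, seed, version, input digests."""
    digests = {}
    for p in inputs:
        p = Path(p)
        if p.exists():
            digests[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    return {
        "stage": stage,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "inputs": digests,
    }


def preprocess(ensemble: StructureEnsemble, config: PipelineConfig):
    """Reference selection + alignment + joint PC-space fit for one ensemble."""
    reference, report = select_reference(ensemble)
    aligned = align_ensemble(ensemble, reference)
    space = fit_pca(aligned, variance_cutoff=config.variance_cutoff, reference=reference)
    return aligned, space, report


@dataclass
class DemoResult:
    """Everything the toy demo computes, for plotting and comparison."""

    seed_histograms: dict[str, WeightedHistogram]
    we_histograms: dict[str, WeightedHistogram]
    final_histograms: dict[str, WeightedHistogram]
    boltzmann: WeightedHistogram
    grid: GridSpec
    extended_grid: GridSpec
    histories: dict[str, WEHistory]
    js_seed_pairs: dict[str, float]
    js_final_pairs: dict[str, float]
    js_final_vs_boltzmann: dict[str, float]
    config: PipelineConfig


def run_toy_demo(
    config: PipelineConfig | None = None,
    n_hist_bins: int = 20,
    styles=("basin_A_only", "basin_B_only", "bimodal_50_50"),
) -> DemoResult:
    """Full pipeline on the 2D double well, one run per biased seed ensemble.

    Each style plays the role of one structure generator: all-one-basin,
    all-other-basin, and 50/50 bimodal.  Every seed is downsampled on a
    common grid, relaxed by WE with the bundled Langevin propagator, and
    reweighted; the three final PC1 distributions are compared pairwise and
    against the quadrature Boltzmann reference.
    """
    cfg = config or PipelineConfig()
    potential = double_well(barrier=cfg.barrier)
    propagator = OverdampedLangevin(
        potential, dt=cfg.dt, friction=cfg.friction, kT=cfg.kT
    )

    seeds = {
        style: biased_seed_ensemble(
            potential, style, cfg.n_seed_points, seed=cfg.seed + 101 + i
        )
        for i, style in enumerate(styles)
    }
    all_points = np.concatenate([pts for pts, _ in seeds.values()])
    grid = build_grid(all_points, n_bins=cfg.n_bins)
    ext_grid = extend_grid(grid, n_pad=cfg.n_pad)

    # common comparison edges over the extended PC1 range
    e = ext_grid.edges[0]
    hist_edges = np.linspace(e[0], e[-1], n_hist_bins + 1)
    boltz = WeightedHistogram(
        edges=hist_edges,
        densities=boltzmann_marginal_histogram(potential, hist_edges),
        label="boltzmann",
    )

    seed_h, we_h, final_h, histories = {}, {}, {}, {}
    for i, (style, (pts, wts)) in enumerate(seeds.items()):
        seed_h[style] = weighted_histogram(pts[:, 0], wts, hist_edges, label=style)

        # downsample: one point per occupied core bin, count weights
        bins_members = {}
        idx = assign_bins(pts, grid)
        for j, b in enumerate(map(tuple, idx)):
            bins_members.setdefault(b, []).append(j)
        rng = np.random.default_rng(cfg.seed + 201 + i)
        states, weights = [], []
        for b in sorted(bins_members):
            members = bins_members[b]
            states.append(pts[members[rng.integers(len(members))]])
            weights.append(len(members) / len(pts))
        we_cfg = WEConfig(
            tau=cfg.tau,
            target_per_bin=cfg.target_per_bin,
            n_iterations=cfg.we_iterations,
            seed=cfg.seed + 301 + i,
        )
        history = run_we(states, np.asarray(weights), propagator, ext_grid, we_cfg)
        histories[style] = history
        we_h[style] = we_final_distribution(
            history, n_final=min(10, len(history)), edges=hist_edges, label=style
        )

        transitions = collect_transitions(history)
        rw_cfg = RWConfig(
            n_clusters=cfg.n_clusters,
            n_iterations=cfg.rw_iterations,
            smoothing=cfg.smoothing,
            seed=cfg.seed + 401 + i,
            variance_cutoff=cfg.variance_cutoff,
            avg_window=min(cfg.rw_avg_window, cfg.rw_iterations),
        )
        result = rw_iterate(transitions, rw_cfg)
        final_h[style] = weighted_histogram(
            transitions.end[:, 0], result.final_weights, hist_edges, label=style
        )

    def pairwise(hs):
        out = {}
        names = list(hs)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                out[f"{names[i]}|{names[j]}"] = js_divergence(hs[names[i]], hs[names[j]])
        return out

    return DemoResult(
        seed_histograms=seed_h,
        we_histograms=we_h,
        final_histograms=final_h,
        boltzmann=boltz,
        grid=grid,
        extended_grid=ext_grid,
        histories=histories,
        js_seed_pairs=pairwise(seed_h),
        js_final_pairs=pairwise(final_h),
        js_final_vs_boltzmann={s: js_divergence(h, boltz) for s, h in final_h.items()},
        config=cfg,
    )
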