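# Methods

This note records the models, algorithms, parameter choices and known
limitations of `ensrect`, in the order the pipeline runs them.

## Problem setting

Given an arbitrary conformational ensemble of one protein (or, in the toy
systems, a point cloud on an analytic energy surface), estimate the
equilibrium distribution of a specified dynamics engine.  "Equilibrium" is
always relative to that engine: for molecular dynamics it is the force
field's Boltzmann ensemble; for the bundled Langevin toys it is
exp(−E/kT)/Z with kT = 1, computable by quadrature.  The pipeline makes no
assumption that the seed ensemble is close to equilibrium — only that it
spans the relevant regions of configuration space well enough for
trajectories started there to connect them.

## Alignment reference and PC space

Pairwise Cα RMSD (Kabsch superposition, proper rotations only — the SVD
rotation is determinant-corrected so reflections never occur) feeds DBSCAN
with `metric="precomputed"`.  The neighborhood radius comes from the
k-distance elbow: for each k in [2, 10] the sorted k-th-nearest-neighbor
distance curve is reduced to the point of maximum perpendicular distance to
its endpoint chord.  Among the (eps, k) candidates the one whose clustering
keeps the largest fraction of members in the main cluster wins, ties to the
smaller k; this selection rule is our choice — the elbow heuristic itself
does not prescribe one.  The reference is the medoid of the largest
cluster (lowest index on ties); if everything is noise we fall back to the
global medoid with a warning.

PCA acts on the flattened 3M-dimensional aligned Cα coordinates, centered
on the ensemble mean (not the reference), unweighted — covariance, not
correlation.  Axis signs follow a fixed convention (largest-magnitude
loading positive) so output is deterministic across eigen-solvers.  The
retained subspace is the smallest one reaching the variance cutoff
(default 0.85).

## Grid downsampling

Per PC dimension, the data range is rounded outward-aware to the nearest
0.1 (half-away-from-zero; a range collapsed by rounding is expanded by 0.1
each way) and split into 10 equal bins.  Bins are half-open [lo, hi) with
the top bin closed and out-of-range points clamped to edge bins — every
point is binnable.  One member per occupied bin is drawn uniformly
(seeded), carrying weight = occupancy/total, so weights are exact rationals
summing to 1.

## Weighted ensemble

The WE grid is the downsampling grid extended by 5 core-width bins per end
per dimension (10×10 → 20×20 = 400 bins).  Each iteration propagates every
walker for τ, records (parent, start/end projection, weight), bins end
projections, and resamples each occupied bin to the target count
(default 8): splitting repeatedly halves the largest-weight walker;
merging repeatedly combines the two smallest, the survivor chosen with
probability proportional to weight.  Both operations are statistically
exact; bin totals are conserved to the last bit (halves are exact in
binary), and the global total is renormalized against a compensated
(fsum) sum each iteration, holding drift below 1e-12 over thousands of
iterations.  There is no recycling and there are no sink states — this is
equilibrium WE; walkers that leave the extended grid are clamped into the
edge bins.

Per-walker random streams derive from (root seed, iteration, walker id),
so results do not depend on execution order; the batched propagation path
draws each walker's noise from its own stream and is bit-identical to
per-walker propagation.  With one bin and target 1, the engine provably
reduces to a single unbiased trajectory.

The propagator contract is two methods, `propagate(state, tau, rng)` and
`project(state)`.  The bundled `OverdampedLangevin` integrates
dx = −∇E/γ dt + sqrt(2 kT dt/γ) η by Euler–Maruyama (defaults dt = 0.01,
γ = 1, kT = 1, dimensionless).  Its discrete stationary distribution
differs from the continuous Boltzmann one by O(dt); at the default step on
the toy surfaces this bias is far below the statistical resolution of the
comparisons we run (and the thermodynamic checks use dt = 0.002).

## Randomized iterative reweighting

Each WE iteration contributes one segment per walker: start and end
projections plus the walker's weight during that iteration — a τ-step
transition sample.  The reweighting loop, per iteration:

1. k-means on segment **end points** with k fresh random centers drawn
   from the data, 10 Lloyd steps, no restarts; start points are assigned
   to the same centers.  Per-iteration polish is pointless: the
   *randomization* of the partition across iterations is what removes
   discretization bias.
2. Cluster transition matrix under current weights:
   T_ij = Σ w(start i → end j) / Σ w(start i).
3. Stationary solve πT = π by the dominant left eigenvector, with strong-
   connectivity check (reducible T → re-draw the clustering; after 100
   failed draws, a structured error advising more WE sampling).
4. Raw update: segments **starting** in cluster i are rescaled by
   π_i / W_i where W_i is their current summed weight — relative weights
   within a cluster are preserved.
5. Smoothing: new = (1−s)·raw + s·(start-cluster mean of raw), s = 0.01 by
   default.  Smoothing damps the multiplicative random walk that
   per-segment weights would otherwise perform under ever-changing
   partitions; without it the weight field stays noisy.
6. Renormalize; record the L1 change.

**Why the update is start-based.**  The self-consistency condition does
not dictate whether the rescaling factor attaches to a segment's start or
end cluster, and both read naturally from the verbal description of the
scheme.  They behave very differently.  A start-based factor is constant
along each row of the weighted transition estimate and cancels in T, so
the update leaves the next iteration's T invariant: the iteration is a
damped fixed-point search whose only driver is genuine inconsistency
between cluster masses and π.  An end-based factor multiplies T's columns,
feeding the update back into the next transition estimate; on slowly
mixing systems this is a positive feedback loop — in our experiments it
drives π to a vertex of the simplex and collapses most segment weights to
zero within tens of iterations.  We therefore rescale by start cluster.
The package's validation properties (fixed point at stationarity,
recovery of analytic stationary vectors from biased initializations,
insensitivity to cluster count) all hold under this choice.

Reported weights are the last iteration's, or (default in the demo) the
mean over a trailing window of 100 iterations, which averages out the
residual per-iteration clustering noise.  Final distributions are
histograms of segment end points under the final weights.

## Synthetic systems

The toy generators stand in for the expensive inputs of a real run:

- `double_well(barrier, separation, transverse_stiffness, asymmetry)`:
  E = barrier·((x/a)²−1)² + ½k_y y², a = separation/2; an optional smooth
  step (width a/12, flat at both minima) raises basin B by ΔE without
  reshaping either basin, so the two-basin Boltzmann ratio is e^(−ΔE) to
  well under 2%.  The Boltzmann reference is trapezoidal quadrature on a
  400×400 grid (normalization error < 1e-6).
- `biased_seed_ensemble`: rejection sampling of the Boltzmann density
  restricted to one basin (or half-and-half), mimicking structure
  generators that oversample a single state.  Default study condition:
  barrier 3 kT, 2000 points per seed, three styles.
- `markov_chain_transitions`: segments drawn from an explicit
  row-stochastic matrix, start states allocated by largest-remainder
  rounding so the aggregated start mass reproduces the requested initial
  weights exactly; centers jittered by Gaussian noise (σ = 0.05).  These
  fixtures have analytic stationary vectors — the ground truth for the
  reweighting tests.
- `synthetic_ca_ensemble`: an idealized Cα helix deformed along random
  orthonormal modes with planted amplitudes, plus noise, each member
  randomly rotated/translated.  The planted coefficients are returned so
  alignment/PCA can be checked against bookkeeping rather than
  eyeballing.

What these toys do **not** emulate: real force-field energetics, side
chains and solvent, metastability hierarchies deeper than two basins, the
anisotropic noise of molecular kinetics, and PDB pathologies (altlocs,
missing residues, insertion codes).  Passing tests demonstrate the
*machinery* — exactness of bookkeeping and convergence of the
reweighting — not force-field accuracy on proteins.

## Numerical choices and degenerate inputs

- Bin conventions are identical everywhere (half-open, top-closed,
  clamped), so histogram comparisons and WE binning agree bin-for-bin.
- Jensen–Shannon divergence is in nats with the 0·log 0 = 0 convention;
  disjoint supports give ln 2.
- Identical members ⇒ zero distance matrix ⇒ the k-distance elbow
  degenerates; we return a minimal positive eps yielding one cluster.
- Medoid and cluster-size ties break to the lowest index.
- Markov-chain eig solves clip numerically negative stationary components
  at zero before renormalizing.
- The demo's operating scale (three seeds of 2000 points, 200 WE
  iterations at τ = 0.5, 2000 reweighting iterations, trailing window
  100) was chosen as the smallest run at which the three final
  distributions agree with the quadrature reference to a few 1e-3 nats;
  larger runs sharpen the agreement but do not change the picture.

## Known limitations

- RiteWeight needs transitions *between* the relevant states in the WE
  data; if the seeds occupy disjoint basins and WE never crosses the
  barrier, the cluster chain is reducible and the solver (correctly)
  refuses rather than fabricating populations.
- The PDB reader expects one chain-consistent atom layout per model and
  rejects ensembles with varying residue counts rather than truncating.
- PCA is linear; strongly curved conformational manifolds may need more
  retained components than the variance cutoff suggests.
- The bundled integrator is first-order (Euler–Maruyama); its O(dt)
  stationary bias is negligible at the shipped step sizes but would not
  be for stiff potentials.
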