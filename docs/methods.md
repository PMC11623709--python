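# Methods

This note documents the models behind `impelo`, the parameters that matter,
the numerical choices, and what the synthetic fixtures can and cannot show
about real planning data.

## Beam model

Proton base data (depth-dose curves, ranges, spot sizes) are
machine-specific and normally measured or Monte-Carlo generated. `impelo`
substitutes an analytic family:

* **Range–energy law.** `R(E) = α E^p` with `α = 0.022 mm/MeV^p`,
  `p = 1.77` — the standard power-law fit to proton CSDA ranges in water
  (≈ 41 mm at 70 MeV, ≈ 320 mm at 225 MeV).
* **Depth dose.** The raw power-law stopping profile
  `(R − z)^{1/p − 1}` is convolved with a Gaussian range-straggling kernel
  of width `σ_R = 0.012 · R^0.935` mm (Bohr-type scaling), then the depth
  axis is rescaled so the distal 80 % point of the smeared curve equals
  `R(E)` *exactly*. This makes the layer's nominal range an exact,
  testable invariant rather than a fitted by-product. One global amplitude
  anchors the family (peak of the 150 MeV curve = 20 dose·mm²/MU); the
  shape-vs-energy behaviour (broader, lower peaks at higher energy) follows
  from the straggling width. The curve support is truncated where it falls
  below 0.1 % of the peak, guaranteed within 30 mm past the range.
* **Spot width.** `σ(z)² = σ_air(z)² + σ_mcs(z)²`. The in-air sigma at
  isocenter decreases with energy, `σ_air(E) = 2 + 5 (70/E)^1.8` mm
  (7 mm → 2.6 mm over the energy grid), and scales linearly with distance
  from the per-axis virtual source (`sad_x = 1900 mm`, `sad_y = 2300 mm` by
  default — scanned beamlines commonly have different magnet-to-isocenter
  distances per axis). Multiple-scattering growth is a monotone cubic in
  `t = z/R`: `σ_mcs = 0.025 R (1.5 t² − 0.5 t³)`, reaching 2.5 % of the
  range at end of range. Only monotonicity and the quadrature structure
  matter to the algorithms; the cubic and its endpoint are configuration.
* **HU calibration.** Piecewise-linear HU → relative electron density with
  anchors (−1000, 0.001), (0, 1.0), (1000, 1.52), (3000, 2.83), clamped at
  the ends. Water maps to density 1 by construction.

None of these constants is fitted to a particular machine; they are chosen
once for physical plausibility and frozen.

## Dose engine

Per spot: the central axis runs from the per-axis virtual sources through
the spot's isocenter-plane position (the axis tilts with lateral position —
the standard divergence of scanned beams). Water-equivalent depth along the
axis is an exact Siddon-style traversal of the density grid; dose at a
voxel is `IDD(wepl) · G(Δx; σ_x) · G(Δy; σ_y)` with lateral offsets
measured from the diverging axis. The central-axis WEPL is reused laterally
— the classical pencil-beam approximation, and the engine's main fidelity
limit in strongly heterogeneous media (it ignores differential range
pull-back across the spot face). Columns drop entries below `10⁻⁴` of the
column maximum by default (configurable; tests that need exactness set 0).

Spot/layer placement covers the target's projection with a regular lateral
lattice (default spacing = the in-air sigma of the middle layer; margin
5 mm) and selects every energy layer whose r80 lies inside the target's
WEPL window extended by the margin; each layer keeps the lattice nodes
whose own WEPL interval contains the layer's range. Blocks are ordered
beam-ascending, energy-descending (distal first); spots row-major — a fixed
deterministic ordering, which the block-indexed algorithms require.

## Objective and solvers

The plan objective is the weighted quadratic over L2, DVH-max and DVH-min
terms described in the README, with doses in percent of prescription. The
violating-voxel rule is the standard sorted-exemption construction: for a
DVH-max term with bound `b` and allowed hot fraction `v` on `K` voxels, the
`⌊vK⌋` hottest voxels are exempt and the remaining voxels above `b` are
penalized; DVH-min mirrors it from below. Floor for exempt counts, stable
sort (ties broken by voxel index): the sets are reproducible bit for bit.

Restricted solves:

* **L2 support projection** — nonnegative least squares on the selected
  blocks, via `scipy.optimize.lsq_linear` (dense BVLS below ~400 columns,
  sparse TRF above). Nonnegativity is imposed even though the idealized
  matching-pursuit projection is unconstrained: intensities are physical
  and the MMU set lies inside the nonnegative cone.
* **DVH + MMU solve** — iterative convex relaxation: freeze the violator
  sets, solve the resulting convex quadratic under the MMU set constraint
  with ADMM, refresh the sets; stop when they no longer change (at most 5
  refreshes by default). The ADMM split is the canonical one for set
  constraints: the x-update solves the support-restricted normal system,
  the z-update is the exact Euclidean projection onto
  `{0} ∪ [Gmin, ∞)` (`0` if `v ≤ Gmin/2`, else `max(v, Gmin)`), followed by
  a scaled dual update with residual-balancing penalty adaptation
  (`ρ` initialized at the mean diagonal of the Hessian). The x-update uses
  a dense Cholesky factorization rather than conjugate gradients: supports
  stay in the low thousands of columns, where one factorization per
  penalty value is both exact and faster than repeated CG sweeps. The
  returned weights are the z iterate, so MMU feasibility is exact set
  membership, never a tolerance. Non-convergence returns the best feasible
  iterate with a flag — it never raises mid-loop.

Everything is deterministic: no random initialization anywhere, so a fixed
seed reproduces a solve bit for bit.

## Greedy energy-layer selection

The layer budget is the hard constraint `‖x‖_BS ≤ N` (number of nonzero
blocks). The selection loop keeps two tracks: a matching-pursuit track
(support `S1`, weights `x1`) driven purely by the least-squares residual of
the L2 system, and an accepted-plan track (`S2`, `x2`) on which the full
DVH+MMU problem is re-solved each time a candidate block is tentatively
added. A candidate is accepted only if the resulting objective is strictly
below the best accepted value; otherwise the accepted track reverts while
the matching-pursuit track keeps the block, so the residual-driven
candidate stream moves past unhelpful layers instead of re-proposing them.
The loop stops when `N` blocks are active, or when the iteration cap
(default: the number of blocks) is exhausted — in that case the best
accepted plan is returned with an explicit under-budget flag. Accepted
objectives are strictly decreasing by construction. The budget is counted
across all beams (the per-beam option is a config flag away in the caller,
but totals are the reported quantity). Inner solves warm-start from the
previous accepted weights; this changes nothing about the fixed points and
speeds the loop up several-fold.

On toy problems with nonnegative orthonormal blocks (disjoint row supports)
and a constant target, block correlations are nonnegative and the
correlation ranking provably equals the per-block objective-reduction
ranking, so the greedy support attains the exhaustive best-support optimum
— that is the regime the optimality tests pin down. On general instances
greedy is only guaranteed to be no better than the exhaustive minimum, and
the tests assert exactly that bound.

## Evaluation

* **DVH / D95.** Empirical (step-function) cumulative DVH;
  `D_q` = largest dose `D` with `volume(dose ≥ D) ≥ q`. No interpolation:
  quantiles are always attained sample values. Plans are normalized by
  `100 / D95(CTV)`; normalization is idempotent and flags any weight it
  pushes into the forbidden MMU gap `(0, Gmin)`.
* **Conformity index.** `CI = V₁₀₀,CTV²/(V_CTV · V₁₀₀)` by voxel counting;
  `V₁₀₀ = 0` returns 0 by convention.
* **3D gamma.** Global normalization (dose difference as a percentage of
  the reference maximum), 10 % low-dose threshold, discrete neighborhood
  search with trilinear interpolation of the evaluated distribution.
  Search step defaults to DTA/10 within a 3·DTA radius: at DTA/5 the
  discrete search was measured to miss ~0.9 percentage points of passing
  voxels against a 0.2 mm exhaustive search on smooth 2 % perturbation
  fields, so the finer default buys sub-0.5-point accuracy at roughly 8×
  the offset count (early termination keeps agreeing voxels cheap).
* **Delivery time.** `switches · ELST + travel/speed + MU/rate`, counting
  only delivered spots (weight > 0) and layers containing at least one;
  switches = delivered layers − beams. Defaults (ELST 1.5 s, 1000 mm/s,
  400 MU/s) give clinically shaped orders of magnitude — tens of seconds to
  minutes per plan — and are deliberately not fitted to any machine; only
  monotone comparisons between plans on the same case are meaningful.

## Synthetic cases

The presets emulate the geometric structure of typical planning scenarios,
not anatomy: an elliptical-cylinder body with an embedded ellipsoidal CTV
(2–2.5 cm scale), one organ-at-risk apiece (kidney-, brainstem-,
esophagus-shaped), a bone shell for the brain case, and a −700 HU
low-density shell around the lung target. Beam angles per preset are the
clinically typical sets (abdomen 90/180/270; brain 45/135/225/315; lung
0/60/90/330). A small seeded jitter on centers and semi-axes makes seeds
geometrically distinct while keeping every case valid; generation is
bitwise deterministic per seed. Default grid spacing is 2 mm (1 mm is a
parameter away) — the test problem sizes (50–70 voxels per axis, 600–900
spots, ~30 blocks) were chosen so a full plan optimizes in seconds while
every algorithmic phenomenon of interest (layer redundancy, MMU gaps, DVH
trade-offs, heterogeneity-induced range spread) is present.

What passing tests on these fixtures show: the algorithms are correct
(against oracles), deterministic, and exhibit the expected qualitative
planning behaviour (budgeted plans trade a bounded objective increase for
strictly shorter delivery). What they do not show: absolute dosimetric
accuracy in patients (no nuclear halo, single-Gaussian lateral kernel,
central-axis WEPL approximation, invented anatomy) or machine-specific
delivery times.

## Known limitations

* Pencil-beam fidelity: no nuclear interaction halo, no double-Gaussian
  lateral model, central-axis WEPL shared across the spot face.
* No range shifter: targets shallower than the 70 MeV range (≈ 40 mm WEPL)
  cannot be covered proximally; the lung preset geometry keeps its target
  below that depth.
* Block budget is global across beams; per-beam budgeting would need a
  small extension of the selection loop.
* The ADMM subproblem is nonconvex for `Gmin > 0`; the solver returns a
  feasible stationary point, not a certified global optimum — the greedy
  acceptance test is what protects overall plan quality.
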