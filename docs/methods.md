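# Methods

## Model

The tissue (or phantom) is modeled as an isotropic linear-elastic body —
plane stress in 2D slices, the full isotropic law in 3D — discretized on a
finite-element mesh whose nodes coincide with (or interpolate) the imaging
pixels.  Each element `k` carries a dimensionless design density `ρ_k`
scaling its Young's modulus through the SIMP parameterization

    E_k = ρ_k^p · E⁰ ,   0 < ρ_min < ρ_k ≤ 1 ,

with the exponent fixed at `p = 1`: unlike structural topology optimization,
the goal is not a 0/1 layout but a continuous stiffness field, so density
and modulus are kept proportional.  Loading is quasi-static; with rapid
loading ramps and high water content, fluid flow is negligible on the
acquisition time scale and near-incompressibility is assumed (`ν = 0.49`).

Measured displacements are prescribed as Dirichlet data on **all boundary
nodes**.  A consequence used throughout: under pure-displacement boundary
conditions the interior solution is invariant to a global scaling of `E⁰`,
so only *relative* stiffness is identifiable.  `E⁰ = 500 Pa` is an arbitrary
baseline; reconstructions are reported normalized to a mean relative
stiffness of 0.5, and contrasts as region-mean ratios, both invariant to
that choice (verified by test).

## Inverse problem

The design objective is the worst weighted displacement mismatch over
internal nodes,

    F = max_{i,c}  w_i |u_exp,ic − u_sim,ic| ,

a min–max criterion that bounds the pointwise model error rather than an
average.  Because `max` is non-smooth, gradients are taken on a p-norm
aggregation (default exponent 12, evaluated in a scaled form that cannot
overflow); the true `F` is always the quantity reported and monitored.

Sensitivities come from a single adjoint solve per iteration: with
`K_ff λ = ∂F̃/∂u_f`, the derivative w.r.t. each density is
`dF̃/dρ_k = −(p ρ_k^{p−1} E⁰) · λ_eᵀ K⁰_e u_e`, using the already-factorized
stiffness (the system is symmetric).  An independent central-difference
oracle confirms the adjoint to ≤1e−5 relative error on small problems.

Element sensitivities are regularized by a cone-shaped (linear-decay)
neighborhood filter of radius 2× the element size, row-normalized — the
standard mesh-independence device; it also encodes the prior that stiffness
varies smoothly at the sub-filter scale.  On the weakly-identified 3D
problem the filter is what selects the physically meaningful smooth
solution among near-equivalent data fits; removing it visibly corrupts
layer ratios even on noise-free data.

### Updates and acceptance

Three update rules are provided:

* `mma` — the closed-form solution of the unconstrained
  method-of-moving-asymptotes separable convex subproblem, with standard
  asymptote adaptation (init 0.5 span, expand 1.2 / shrink 0.7), a
  move limit of 0.1 per iteration, and a backtracking line search.
* `pg` — Barzilai–Borwein projected gradient with the same move limit and
  line search.
* `lbfgs` — bound-constrained quasi-Newton (L-BFGS-B) descent of the
  filtered surrogate.

`method="auto"` (the default) picks `lbfgs` for clean data and `mma` for
noisy data (see stopping below).  The split reflects their characters:
quasi-Newton converges far deeper on deterministic problems (on the 3D
cylinder it reaches a 1.92 layer ratio where 400 move-limited iterations
reach 1.83), while the move-limited methods, which accept a step **only if
the true min–max objective decreases** (the surrogate may regress by at
most 5%), are deliberately conservative on noisy data, where descending
further means fitting noise.

### Stopping: the discrepancy floor

Smoothed MRI displacement data carry a quantifiable residual error.  Both
smoothers return a per-pixel uncertainty estimate of their own output:

* robust LOWESS — the smoother is linear in the data given its final robust
  weights, so the fit's noise SD is `σ̂ · ‖L_i‖₂` (σ̂ = robust residual SD);
  to this a plug-in estimate of the local-linear smoothing bias is added,
  namely the difference to a local *quadratic* refit;
* mask-normalized Gaussian — analogous, with a `σ/√2` scale-halving bias
  estimate and the kernel's ℓ2 norm.

The inverse model turns this map into (a) per-node objective weights, the
median-normalized reciprocal of the local uncertainty — unreliable
(edge/outlier) nodes are down-voted exactly as the weighted objective
intends — and (b) a stopping floor equal to the median uncertainty: the fit
terminates once every weighted residual is inside the data's own error band
(Morozov's discrepancy principle).  This floor, not the iteration cap, is
what controls the noise replicate-to-replicate variability of the maps;
without it every convergent optimizer ends up reproducing smoothed noise as
spurious stiffness texture.  Clean (uncertainty-free) inputs have no floor
and converge to the solver tolerance.

Additional stops: relative objective improvement below 1e−4 for 5
consecutive iterations; no backtracked step improving the objective
(stationary under the filtered update); or the iteration cap — 100 for 2D
move-limited runs, 400 in 3D (per-iteration progress is slower with
volumetric elements), 200 for quasi-Newton.  On cap exhaustion the
best-so-far map is returned with `converged=False`.

## Meshing

Rectangular masks get structured bilinear quad (2D) / trilinear hex (3D)
lattices; quadratic serendipity quads are available but not default
(simpler assembly at equal accuracy for these problems).  Irregular masks
are meshed by connecting the masked pixel centers: every grid cell whose
corners are all masked is split along a fixed diagonal into 2 triangles or
6 tetrahedra (the Kuhn decomposition — a valid Delaunay triangulation of
the lattice that, unlike a generic Delaunay of cospherical grid points, is
conforming and sliver-free).  Pixel-aligned quad/hex meshes of irregular
masks are also supported; the 3D cylinder phantom uses bricks because
linear tetrahedra lock near `ν = 0.49` and measurably blur identifiability
(noise-free layer ratio 1.41 with tets vs 1.92 with bricks on identical
data).  Selective-reduced integration is available as a flag for
quad4/hex8.

Elements with non-positive measure, centered outside the mask, or with an
edge shorter than the minimum-feature threshold are culled.  The threshold
defaults to 0.5 mm but is capped at 0.9× the pixel pitch, so grids finer
than 0.5 mm are not annihilated; it only acts on coarse/irregular
geometries.

Boundary nodes are those on facets owned by exactly one element.  Total
mesh measure matches the masked area/volume to within a one-pixel shell
(tested).

## Phantoms

The generator reproduces the validation suite geometry: a 6 × 6 mm bilayer
(1000 Pa top / 500 Pa bottom, 0.15 mm pixels matching the stated imaging
resolution), stiff circular inclusions (1000 and 1500 Pa on a 500 Pa
background), a soft slender fissure-like inclusion (200 Pa) on a 500→1000 Pa
bottom-to-top gradient, a uniform null case, and a two-layer 3D cylinder
with a 2:1 modulus ratio (radius 5 mm, height 6 mm, top third stiff, 0.6 mm
voxels).  Inclusion positions/sizes are package defaults (the sources state
only moduli); they are parameters of the spec objects.

Loading is the indentation preset: bottom face fully fixed, top face
displaced by 15% of the thickness with stick contact, lateral faces free.
Generated displacement fields satisfy the prescribed values exactly at
boundary pixels, and noise (experimental level σ = 0.1 mm, Gaussian,
per component) is added at **all** masked pixels, boundary included, to
mimic the acquisition.  Same spec + seed is bit-reproducible.

What the phantoms do *not* emulate: MRI signal formation (only the phase
arithmetic of displacement encoding is implemented), material nonlinearity
(agarose/PDMS hyperelasticity), anisotropy, contact between bodies, and
fluid flow.  Passing tests therefore demonstrate correctness of the
reconstruction pipeline under its own forward model — an inverse-crime
validation, as in the original simulation studies — not robustness to
constitutive misspecification.

## Error analysis

Monte-Carlo: per replicate, fresh noise → smoothing → inversion →
normalization; then

* bias = RMS over elements of (across-replicate mean map − normalized
  truth) — the replicate-mean variant is primary; the per-replicate RMS
  variant is also computed;
* precision = pooled per-element across-replicate SD (the SD of
  per-replicate RMSE is recorded as an alternative reading).

The acceptance script uses 30 replicates (≈1 s each at 40×40 elements);
the module default is 100.  With the default pipeline the bilayer gives
bias ≈ 0.07 and precision ≈ 0.07 on the mean-0.5 scale, with the bias map
strongly elevated at the layer interface.  A known divergence: elevation of
the bias at the *fixed bottom boundary* is not observed here — the
uncertainty-weighted objective keeps near-boundary elements consistent with
their (well-determined) data instead of leaving them at the initialization.

Cotter's method ranks pipeline factors by the systematic fractional
replicate two-level design (2m+2 runs; odd/even contrasts
`C_o = (Δhigh + Δlow)/4`, `C_e = (Δhigh − Δlow)/4`, importance
`M = |C_o| + |C_e|`).  Default factor levels: noise σ {0.02, 0.2} mm,
smoothing {Gaussian, LOWESS}, ν {0.3, 0.49}, filter radius {1×, 4×} element
size, mesh density {0.3, 0.6} mm, iteration cap {30, 100}.  Constitutive-law
and 2D-assumption factors are outside the linear-elastic scope of this
package.

## Parameter defaults

| parameter | default | units | rationale |
|---|---|---|---|
| `E0` | 500 | Pa | arbitrary baseline (relative stiffness only) |
| `nu` | 0.49 | – | near-incompressible tissue/gel under rapid ramps |
| `penal` (p) | 1 | – | modulus linear in density; no 0/1 penalization |
| `rho_min` | 0.01 | – | keeps the stiffness matrix definite |
| `rho_init` | 0.5 | – | uninformative start, center of the box |
| `aggregation_exponent` | 12 | – | tight, stable smooth-max surrogate |
| `filter_radius` | 2 × element size | mm | mesh-independence + smoothness prior |
| `move_limit` | 0.1 | – | conservative per-iteration density change |
| `objective_tolerance` | 1e−4 | – | stationarity threshold (5-iteration patience) |
| LOWESS window | 150 | pixels | stated acquisition-processing window |
| robust iterations | 3 | – | standard bisquare re-weighting practice |
| noise σ (experiments) | 0.1 | mm | experimental MRI displacement noise level |
| indentation depth | 15% | of thickness | validation loading protocol |

## Numerical choices and degenerate inputs

* Sparse direct factorization (SuperLU) of the condensed free-DOF block;
  the factorization is shared between forward and adjoint solves and its
  index structure is cached across Monte-Carlo replicates.
* Dirichlet data may prescribe single components (NaN = free), enabling
  roller conditions; prescribed DOFs are reproduced exactly by
  construction.
* Phase unwrapping output is snapped to exact 2π congruence with its input;
  disconnected mask components are unwrapped independently with a warning
  (their mutual offset is unidentifiable).
* LOWESS with a window larger than a mask region shrinks to the region and
  warns; a zero robust residual scale degenerates gracefully to
  indicator weights.
* Region labels on a map with an empty region, encoding with a zero net
  gradient, empty/disconnected masks, inverted elements, and erosion to an
  empty mask all raise typed errors rather than propagate NaNs.
* Normalization clips to (0, 1] after rescaling to mean 0.5; the clip is
  inactive for all phantom contrasts used here.

## Problem sizes used in the shipped runs

Unit tests run the bilayer at 0.3 mm (20×20 elements) where resolution is
immaterial, and at the full 0.15 mm (40×40) for the Monte-Carlo and
noise-free ratio checks; gradient checks use an 8×8 mesh where central
differences are exact enough; the cylinder runs at its native 0.6 mm voxels
(1830 bricks).  These are the package's validation sizes; all scale up by
changing `resolution`/`target_element_size`.

## Known limitations

* Absolute stiffness requires stress (force) boundary data — out of scope;
  only relative maps and ratios are produced.
* Linear elasticity only; hyperelastic or anisotropic laws and multi-body
  contact are not implemented.
* Linear tetrahedra near `ν = 0.5` lock; prefer bricks (the default for
  voxel masks in the phantoms) or lower ν where appropriate.
* The discrepancy floor depends on the smoother's uncertainty estimate;
  heavily non-Gaussian artifacts should instead be cropped
  (`crop_artifact_margin`) or down-weighted (`outlier_weights`).
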