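# Methods

## Model and conventions

A deformable-registration transformation is represented as φ(x) = x + d(x)
with a three-component displacement field d on a regular 3-D grid.  All
displacement arithmetic is in **voxel units**: component c displaces along
array axis c, measured in multiples of that axis's spacing.  Physical spacing
(mm per voxel) enters only in landmark error reporting.  Arrays are indexed
(x1, x2, x3) with 0-based indices; file readers convert into this convention
(SimpleITK's slice-first layout is transposed, mm-stored fields are divided
componentwise by the spacing).

The per-voxel volume-change factor is the determinant of the forward-
difference Jacobian

    J̃_ij(x_k) = δ_ij + d^(i)(x_k + e_j) − d^(i)(x_k),

and the ventilation metric is V(x_k) = det J̃(x_k) − 1, the estimated
fractional volume change of the unit voxel.  The approximation is exact for
affine transformations (constant Jacobian) and first-order accurate
otherwise.  Where x_k + e_j leaves the grid the neighboring value is
replicated, so the difference is zero and the affected entry reverts to the
identity; how to difference at the boundary is a genuinely open choice, and
replication was picked because it defines J̃ everywhere without inventing
data.  Voxels relying on replication are excluded from the constrained set
(below) and flagged by `GridDomain.interior()`.

Diffeomorphic convention: a valid volume-change (target Jacobian) image is
strictly positive; generators validate det J̃ > 0 on the interior and reject
parameterizations that fold.

## Perturbation stability bound

Perturbing a single displacement vector, d(x_k) → d(x_k) − h, adds h to every
forward-difference entry containing −d(x_k), i.e. J̃ → J̃ + h·1ᵀ.  The induced
metric change obeys

    |V_h − Ṽ(x_k)| ≤ (3√3/2) ‖h‖ · max_i ∏_{j≠i} (1 + ‖∇d̃^(j)(x_k)‖),

where ∇d̃^(j) is the discrete forward-difference gradient of component j (the
only gradient the discrete model defines) and the norms are Euclidean — the
norm in the bound is not otherwise specified, and the Euclidean choice
matches the derivation's use of cross-product magnitudes.  The implementation
computes both forms of the perturbed metric (rank-one update and in-place
recompute) and tests their equality; the displayed rank-one form is used at
runtime.  `empirical_max_change` verifies the bound by sampling perturbation
directions uniformly on the sphere (normalized standard normals, seeded),
always including the six ±axis directions so the known worst axis-aligned
case is never missed by chance.

## Constrained optimization

The solver fits a field to a priori fidelity data y_i ≈ d(x_i) (the stand-in
for an upstream registration's output) under per-voxel equality constraints
det J̃(x_k) = f(x_k):

    min_d Σ_{i∈I} ‖d(x_i) − y_i‖² + α Σ_j ‖A d̃_j‖²   s.t.  det J̃(x_k; d) = f(x_k).

Design choices:

* **Squared regularizer.**  The quadratic ‖A d̃_j‖² is used in both the
  constrained and unconstrained problems; it is what makes the unconstrained
  fit a strictly convex least-squares problem with a unique solution.
* **Laplacian.**  A is the centered 7-point Laplacian with zero-normal-
  derivative (Neumann) boundary conditions via replicated ghost values,
  assembled as a Kronecker sum of 1-D stencils.  Its null space is the
  constants, so as α → ∞ each component tends to the mean of its fidelity
  values.
* **Constrained set.**  Constraints are enforced only at voxels whose three
  forward neighbors lie inside Ω; the Jacobian stencil is not defined beyond
  the grid, and constraining replicated entries would constrain phantom data.
* **Unconstrained fit.**  (Sᵀ S + α AᵀA) d̃_j = Sᵀ y_j per component, solved
  by sparse LU (one factorization, three solves).  α = 0 demands fidelity
  data at every voxel (pure interpolation); anything less is singular and is
  rejected rather than regularized silently.
* **Augmented Lagrangian.**  Inner subproblems
  L(d) = fidelity + regularizer + Σ λ_k c_k + (μ/2) Σ c_k² are minimized by
  L-BFGS with analytic gradients: ∂det/∂J̃ is the cofactor matrix, and each
  constraint's gradient scatters onto the ≤ 12 displacement unknowns in its
  stencil (+cof_ij at x_k + e_j, −Σ_j cof_ij at x_k).  The outer loop applies
  the first-order multiplier update λ_k ← λ_k + μ c_k and multiplies μ by 10
  whenever the max violation fails to shrink below 0.25× its previous value;
  the inner gradient tolerance tightens geometrically (×0.2 per outer
  iteration from 1e−4).  Defaults: μ₀ = 10, constraint tolerance
  max|det − f| ≤ 1e−3, at most 20 outer iterations.  These are classical
  augmented-Lagrangian settings; all are overridable and logged.
* **No positivity guard during iterations.**  det > 0 is implied at
  convergence by f > 0 plus the tolerance; the final minimum determinant is
  recorded in the solver state rather than enforced along the way.
* **Determinism.**  Nothing in the solve draws randomness; identical inputs
  and options give bitwise-identical trajectories.  Non-convergence returns
  the best iterate with an explicit flag, never a silent success.
* Existence/uniqueness of the constrained problem is not guaranteed
  (nonconvex equality constraints); the solver reports feasibility and
  objective history and makes no global-optimality claim.

Target Jacobian builders: Gaussian-smoothed unconstrained Jacobian
(G_σ ∗ det J̃(·; d_unc)); bound-clipped-then-smoothed targets, which stay in
[LB, UB] because mask-renormalized smoothing is a convex combination; and
correlation targets f = a*·g + b* with (a*, b*) the least-squares line of the
unconstrained Jacobian on the functional image g over Ω (Pearson correlation
is the natural induced notion for an affine map, and fits/correlations are
restricted to the mask).  A non-positive correlation target fails loudly with
the offending voxel count; an optional epsilon floor (off by default) clamps
instead and is visible in the validation report.  Smoothing truncates the
Gaussian at 4σ and renormalizes the kernel so constants are preserved and no
mass leaks across the mask boundary.

## Landmark accuracy

Landmark error is ‖(φ(p_ref) − p_target) ⊙ spacing‖₂ in mm, with d evaluated
by trilinear interpolation at continuous positions (exact at grid nodes —
the natural regularity class for these fields; nothing higher-order is
warranted).  The reported standard deviation divides by n (population
convention, common in target-registration-error reporting); the sample
convention is a flag away.  The field maps reference-phase points toward
target-phase positions, so landmark files load unambiguously
(whitespace-delimited text, 1-based indices by default).

## Synthetic study conditions

The generators stand in for the real study inputs (a 4DCT pair, an upstream
DIR's displacements, a SPECT perfusion image, expert landmarks), which are
not shipped.  Default study scale: grids of 12³–24×24×12 voxels with spacing
(0.97, 0.97, 2.5) mm — the axial voxel dimensions typical of thoracic 4DCT —
on the package's desk-scale grids; the method is scale-free in voxel units,
and these sizes keep every experiment in seconds-to-minutes on one CPU.

* **Contraction case** (`make_contraction_case`): a uniform volumetric
  contraction with mean Jacobian ≈ 0.79 (the mean Jacobian a thoracic
  exhale-to-inhale registration typically produces) overlaid with seeded
  sinusoid modes giving Jacobian std ≈ 0.09 and genuine spatial structure.
* **Fidelity data**: y_i = d(x_i) + N(0, σ²) at a seeded 20 % of voxels with
  σ = 0.1 voxels — sub-voxel noise of the order of a good DIR's landmark
  accuracy.
* **Functional image** (`make_functional_image`): Gram–Schmidt mixing of
  standardized Jacobian values with seeded smooth noise hits the requested
  *sample* correlation exactly (to float precision), so correlation targets
  are testable without sampling slack; ρ = −0.29 is the default, a weak
  negative correlation of the kind perfusion imaging shows against
  unconstrained CT ventilation.
* **Landmarks**: reference points sampled continuously in the grid, targets
  φ(reference) plus optional annotation noise.
* **Regularization weight**: α = 0.1 for the study experiments — with 20 %
  fidelity coverage it recovers the ground-truth field to ≈ 0.04 voxels mean
  error while leaving realistic Jacobian spread (stronger smoothing flattens
  the Jacobian image; none at all amplifies the fidelity noise).  α is
  recorded in every experiment config/report.

What the synthetic cases do **not** emulate: CT intensities (no image
similarity anywhere in the method), sliding motion and discontinuities at the
pleura, mask geometries of real lungs, spatially correlated annotation error,
or an upstream DIR's systematic (non-Gaussian) error structure.  Passing
tests therefore demonstrate the numerical properties of the operators and
solver under smooth diffeomorphic conditions, not clinical performance.

## Numerical details and degenerate inputs

* Forward differences, determinants and cofactors are evaluated in closed
  form (vectorized 3×3 expansion); agreement with naive per-voxel loops is
  tested to 1e−12.
* NIfTI-1 stores voxel spacing in float32, so mm↔voxel conversions through
  `.nii/.nii.gz` are good to single precision; MetaImage round-trips are
  exact.  Values themselves round-trip bitwise in both formats (float64).
* Degenerate inputs fail loudly: non-finite fields/images, masks with no
  voxels, fidelity indices off-grid or duplicated, constant functional
  images (degenerate line fit), non-positive targets, α = 0 with partial
  fidelity coverage, folding synthetic amplitudes.
* Sub-grid extents (< 2 per axis) are rejected; an axis of length 2 already
  makes every voxel boundary-adjacent along it.

## Known limitations

* The stability bound is single-voxel; simultaneous multi-voxel perturbation
  theory is out of scope.
* The solver enforces equality targets only; inequality bounds enter through
  the clipped target construction, not as solver-level inequalities.
* No intensity-based (HU) ventilation and no image-similarity term.
* Convergence of the augmented Lagrangian on these nonconvex constraints is
  practical, not proven; the convergence report is the contract.
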