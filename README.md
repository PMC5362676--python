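# ventjac

Transformation-based CT ventilation imaging and its numerical stability.

CT-derived ventilation infers regional lung function from deformable image
registration (DIR) of inhale/exhale 4DCT phases: the transformation
φ(x) = x + d(x) magnifies each voxel's volume by the Jacobian factor
det J(x; d), so

    V(x_k) = det( J̃(x_k; d) ) − 1

estimates the specific (fractional) volume change of voxel x_k, with J̃ the
forward-difference Jacobian of the displacement field d in voxel units.  This
package implements that metric together with two tools for studying how
*stable* it is with respect to the DIR solution:

1. **A single-voxel perturbation bound.**  Replacing d(x_k) by d(x_k) − h
   changes the metric by at most

       |V_h − Ṽ(x_k)| ≤ (3√3 / 2) ‖h‖ · max_i ∏_{j≠i} (1 + ‖∇d̃^(j)(x_k)‖),

   so a one-voxel change of a *single* displacement vector can swing the
   metric by 1.0 — the difference between zero volume change and a 100 %
   volume increase.  The bound and a Monte-Carlo verification over sampled
   perturbation directions are provided.

2. **A Jacobian-constrained optimization method** that *manufactures*
   displacement fields with user-defined Jacobian images: given fidelity data
   y_i ≈ d(x_i) from an upstream DIR and a strictly positive target image
   f(x), it solves

       min_d Σ_{i∈I} ‖d(x_i) − y_i‖² + α Σ_j ‖A d̃_j‖²
       s.t.  det( J̃(x_k; d) ) = f(x_k)  on Ω,

   (A = 7-point Neumann Laplacian) by the augmented Lagrangian method with
   analytic cofactor gradients.  Target builders cover Gaussian-smoothed,
   bound-clipped (contraction/expansion) and correlation-forcing targets
   f = a*·g + b*, the latter making the ventilation image correlate
   *perfectly* with any functional image g (e.g. SPECT perfusion).

Landmark-based spatial accuracy (mm target registration error with trilinear
interpolation), seeded synthetic study cases with closed-form ground truth,
and MetaImage/NIfTI I/O round out the toolkit.  The headline phenomenon the
tools expose: displacement fields with *similar sub-voxel spatial accuracy*
can produce ventilation images with *very different physical content*.

## Worked example

A seeded 12³ synthetic study case: a contraction-flavoured ground-truth field
(mean Jacobian ≈ 0.79), noisy fidelity samples at 20 % of voxels, and the two
manufactured-ventilation experiments.

```python
import numpy as np
from ventjac import (GridDomain, ScalarImage, SolverOptions, BoundSpec,
                     bound_constraint, correlation_constraint, fit_linear_map,
                     fit_unconstrained, forward_jacobian, jacobian_determinant,
                     landmark_error_stats, solve_constrained)
from ventjac.synthetic import (make_contraction_case, make_functional_image,
                               make_landmarks, sample_fidelity)

domain = GridDomain((12, 12, 12), spacing=(0.97, 0.97, 2.5))
truth, _ = make_contraction_case(domain, seed=0)
fidelity = sample_fidelity(truth, fraction=0.2, noise_sigma=0.1, seed=1)
landmarks = make_landmarks(truth, count=100, seed=3)

unc = fit_unconstrained(fidelity, alpha=0.1, domain=domain)
unc_det = ScalarImage(domain, jacobian_determinant(forward_jacobian(unc)).values)
roi = domain.interior()

# experiment 1: contraction bounds LB=0.5, UB=1.0
f_bounds = bound_constraint(unc_det, BoundSpec(0.5, 1.0, sigma=1.0))
con, state = solve_constrained(fidelity, f_bounds, SolverOptions(alpha=0.1),
                               domain=domain, initial=unc)
det = jacobian_determinant(forward_jacobian(con)).values
print(f"contraction: converged={state.converged} "
      f"max|det-f|={state.violation_history[-1]:.1e}")
print(f"  Jacobian mean (std): unconstrained {unc_det.values[roi].mean():.2f} "
      f"({unc_det.values[roi].std():.2f}) -> constrained {det[roi].mean():.2f} "
      f"({det[roi].std():.2f}), range [{det[roi].min():.2f}, {det[roi].max():.2f}]")

# experiment 2: force perfect correlation with a functional image g
g = make_functional_image(unc_det, rho=-0.29, seed=2, mask=roi)
f_corr = correlation_constraint(g, fit_linear_map(g, unc_det, roi), roi)
con2, state2 = solve_constrained(fidelity, f_corr, SolverOptions(alpha=0.1),
                                 domain=domain, initial=unc)
det2 = jacobian_determinant(forward_jacobian(con2)).values
r0 = np.corrcoef(unc_det.values[roi], g.values[roi])[0, 1]
r1 = np.corrcoef(det2[roi], g.values[roi])[0, 1]
e0 = landmark_error_stats(unc, landmarks)[0]
e1 = landmark_error_stats(con2, landmarks)[0]
print(f"correlation: corr(det, g) {r0:.2f} -> {r1:.2f}; "
      f"landmark error {e0:.2f} mm -> {e1:.2f} mm")
```

Output:

```
contraction: converged=True max|det-f|=5.8e-04
  Jacobian mean (std): unconstrained 0.80 (0.08) -> constrained 0.80 (0.06), range [0.63, 0.95]
correlation: corr(det, g) -0.29 -> -1.00; landmark error 0.10 mm -> 0.16 mm
```

Reading this: the bound constraint pins every Jacobian value into [0.5, 1.0]
and *narrows* the histogram (std 0.08 → 0.06) while the mean volume change is
untouched; the correlation constraint drives the Jacobian–functional-image
correlation from −0.29 to a manufactured −1.00.  In both cases the landmark
error moves by a small fraction of a voxel — spatially accurate DIR solutions
with very different ventilation content.

## Command line

```
ventjac synth            # write a full synthetic study case
ventjac jacobian         # Jacobian / ventilation image of a field
ventjac perturb-bound    # stability bound vs Monte-Carlo empirical max, CSV
ventjac make-constraint  # smooth | bounds | correlation target builders
ventjac fit-unconstrained
ventjac fit-constrained  # augmented Lagrangian solve + convergence report
ventjac accuracy         # landmark mm error statistics
ventjac run-experiment   # full pipeline from a YAML/JSON config
```

Vector and scalar volumes are read/written as MetaImage (`.mha`) or NIfTI
(`.nii`/`.nii.gz`); landmark files are whitespace-delimited text (1-based by
default); fidelity data is CSV (`i1,i2,i3,y1,y2,y3`).

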