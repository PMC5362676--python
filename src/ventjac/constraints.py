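"""Builders for target Jacobian images f(x).

A target Jacobian image assigns every voxel of Omega its desired volume-change
factor.  Three constructions are provided, each derived from the Jacobian
image of an unconstrained fit:

* a Gaussian-smoothed copy of the unconstrained Jacobian,
* a bound-clipped copy (contraction when UB <= 1, expansion when LB >= 1),
  optionally smoothed, which stays inside [LB, UB], and
* the least-squares affine rescaling of a functional image g (e.g. a
  perfusion scan), which by construction correlates perfectly with g.

Targets must be strictly positive on Omega (the diffeomorphic convention);
``validate_constraint`` checks this and is run before any constrained solve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .grid import GridDomain, ScalarImage, gaussian_smooth

__all__ = [
    "BoundSpec",
    "LinearMap",
    "ConstraintValidityError",
    "DegenerateFitError",
    "smoothed_constraint",
    "clip_to_bounds",
    "bound_constraint",
    "fit_linear_map",
    "correlation_constraint",
    "validate_constraint",
]


class ConstraintValidityError(ValueError):
    """A target Jacobian image violates strict positivity on Omega."""


class DegenerateFitError(ValueError):
    """The least-squares line fit is degenerate (constant functional image)."""


@dataclass(frozen=True)
class BoundSpec:
    """Jacobian bounds LB <= det <= UB and the smoothing width applied after clipping."""

    LB: float
    UB: float
    sigma: float = 0.0

    def __post_init__(self):
        if not (np.isfinite(self.LB) and np.isfinite(self.UB) and np.isfinite(self.sigma)):
            raise ValueError("bounds and sigma must be finite")
        if not (0 <= self.LB < self.UB):
            raise ValueError(f"need 0 <= LB < UB, got LB={self.LB}, UB={self.UB}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @property
    def diffeomorphic(self) -> bool:
        """True when LB > 0, i.e. the clipped target is strictly positive."""
        return self.LB > 0


@dataclass(frozen=True)
class LinearMap:
    """Affine intensity map f = a * g + b fitted by least squares."""

    slope: float
    intercept: float

    def __post_init__(self):
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("slope/intercept must be finite")

    @property
    def degenerate(self) -> bool:
        return self.slope == 0.0


def _omega(domain: GridDomain, mask: Optional[np.ndarray]) -> np.ndarray:
    if mask is not None:
        return np.asarray(mask, dtype=bool)
    return domain.omega()


def smoothed_constraint(unc_jac: ScalarImage, sigma: float) -> ScalarImage:
    """Smoother variant of the unconstrained Jacobian: f = G_sigma * det(J(x; d_unc))."""
    om = unc_jac.domain.omega()
    if np.any(unc_jac.values[om] <= 0):
        n_bad = int(np.sum(unc_jac.values[om] <= 0))
        raise ConstraintValidityError(
            f"unconstrained Jacobian not strictly positive on Omega ({n_bad} voxels)"
        )
    return gaussian_smooth(unc_jac, sigma)


def clip_to_bounds(unc_jac: ScalarImage, spec: BoundSpec) -> ScalarImage:
    """Three-case clip of the Jacobian image into [LB, UB]."""
    return ScalarImage(unc_jac.domain, np.clip(unc_jac.values, spec.LB, spec.UB))


def bound_constraint(unc_jac: ScalarImage, spec: BoundSpec) -> ScalarImage:
    """Clip into [LB, UB], then smooth; the result stays inside [LB, UB].

    Mask-renormalized smoothing is a convex combination of in-Omega values,
    so the interval is preserved exactly.
    """
    clipped = clip_to_bounds(unc_jac, spec)
    return gaussian_smooth(clipped, spec.sigma)


def fit_linear_map(
    g: ScalarImage, unc_jac: ScalarImage, mask: Optional[np.ndarray] = None
) -> LinearMap:
    """Least-squares line a* g + b* ~= det(J(x; d_unc)) over masked voxels."""
    om = _omega(g.domain, mask)
    gv = g.values[om]
    jv = unc_jac.values[om]
    if gv.size < 2 or np.ptp(gv) == 0:
        raise DegenerateFitError("functional image is constant on Omega; line fit undefined")
    slope, intercept = np.polyfit(gv, jv, 1)
    return LinearMap(float(slope), float(intercept))


def correlation_constraint(
    g: ScalarImage,
    lin: LinearMap,
    mask: Optional[np.ndarray] = None,
    epsilon_floor: Optional[float] = None,
) -> ScalarImage:
    """Target Jacobian f = a* g + b*, perfectly correlated with g.

    Fails when f is not strictly positive anywhere in Omega, reporting the
    offending voxel count; passing ``epsilon_floor`` instead clamps
    f <- max(f, epsilon) and is recorded by the caller's validation report.
    """
    f = lin.slope * g.values + lin.intercept
    om = _omega(g.domain, mask)
    n_bad = int(np.sum(f[om] <= 0))
    if n_bad and epsilon_floor is None:
        raise ConstraintValidityError(
            f"correlation constraint non-positive at {n_bad} voxels in Omega; "
            "adjust the functional image scaling or use an epsilon floor"
        )
    if epsilon_floor is not None:
        f = np.maximum(f, float(epsilon_floor))
    return ScalarImage(g.domain, f)


def validate_constraint(f: ScalarImage, mask: Optional[np.ndarray] = None) -> dict:
    """Report strict positivity/finiteness of a target Jacobian on Omega.

    Returns a dict with pass/fail, min/max/mean over Omega, and the voxel
    indices (up to 10) of any violations.
    """
    om = _omega(f.domain, mask)
    vals = f.values[om]
    bad = ~np.isfinite(f.values) | (f.values <= 0)
    bad &= om
    locs = np.argwhere(bad)
    return {
        "passed": locs.shape[0] == 0,
        "n_violations": int(locs.shape[0]),
        "violation_voxels": [tuple(int(i) for i in v) for v in locs[:10]],
        "min": float(np.min(vals)),
        "max": float(np.max(vals)),
        "mean": float(np.mean(vals)),
        "n_omega": int(vals.size),
    }
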