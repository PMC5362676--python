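"""Seeded generators for every input the pipeline needs.

These stand in for the real study inputs — a 4DCT inhale/exhale pair, an
upstream registration's displacement estimates, a perfusion scan, and expert
landmark annotations — with fields whose ground truth is known in closed
form or by construction:

* affine fields (constant Jacobian, for which forward differences are exact),
* separable sinusoid fields (smooth, nonlinear, non-uniform motion with an
  analytic continuous Jacobian),
* functional images with an exactly prescribed sample correlation to a given
  Jacobian image (Gram-Schmidt mixing),
* noisy fidelity samples and landmark pairs consistent with a ground-truth
  field.

All generators are deterministic given their seed, and every generated field
is validated to have a strictly positive forward-difference Jacobian
determinant (the diffeomorphic convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np

from .accuracy import LandmarkSet, map_points
from .grid import (
    DisplacementField,
    GridDomain,
    ScalarImage,
    det3,
    forward_jacobian,
)
from .solver import FidelityData

__all__ = [
    "DEFAULT_SHAPE",
    "DEFAULT_SPACING",
    "make_affine_field",
    "make_sinusoid_field",
    "make_smooth_random_field",
    "make_contraction_case",
    "make_functional_image",
    "sample_fidelity",
    "make_landmarks",
]

# Desk-scale default study grid: Table-style axial voxel dimensions on a
# small grid; the method is scale-free in voxel units.
DEFAULT_SHAPE: Tuple[int, int, int] = (24, 24, 12)
DEFAULT_SPACING: Tuple[float, float, float] = (0.97, 0.97, 2.5)


class NonDiffeomorphicFieldError(ValueError):
    """A generated field has non-positive Jacobian determinant somewhere."""


def _check_positive_det(fld: DisplacementField, where: str) -> None:
    det = det3(forward_jacobian(fld).entries)
    interior = fld.domain.interior()
    if np.any(det[interior] <= 0):
        k = np.argwhere(interior & (det <= 0))[0]
        raise NonDiffeomorphicFieldError(
            f"{where}: det(J) <= 0 at voxel {tuple(int(i) for i in k)} "
            f"(min {det[interior].min():.4f}); reduce amplitudes"
        )


def _coords(domain: GridDomain) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    return np.meshgrid(*[np.arange(n, dtype=float) for n in domain.shape], indexing="ij")


def make_affine_field(
    M: np.ndarray, b: Sequence[float], domain: GridDomain
) -> Tuple[DisplacementField, float]:
    """Affine field d(x) = (M - I) x + b; returns (field, det(M)) as ground truth."""
    M = np.asarray(M, dtype=float).reshape(3, 3)
    b = np.asarray(b, dtype=float).reshape(3)
    detM = float(np.linalg.det(M))
    if detM <= 0:
        raise NonDiffeomorphicFieldError(f"det(M) = {detM:.4f} <= 0")
    X = np.stack(_coords(domain))  # (3, n1, n2, n3)
    A = M - np.eye(3)
    data = np.einsum("ij,jabc->iabc", A, X) + b[:, None, None, None]
    return DisplacementField(domain, data), detM


@dataclass(frozen=True)
class SinusoidField:
    """Separable sinusoid displacement with analytic partial derivatives.

    Component i is  d^(i)(x) = a_i * prod_j s_ij(x_j)  with
    s_ij(t) = sin(2 pi f_ij t / n_j + phi_ij) when f_ij != 0 and 1 otherwise.
    """

    amplitudes: np.ndarray   # (3,)
    frequencies: np.ndarray  # (3, 3) cycles across the grid, 0 = inactive
    phases: np.ndarray       # (3, 3)
    shape: Tuple[int, int, int]

    def _factor(self, i: int, j: int, t: np.ndarray, deriv: bool) -> np.ndarray:
        f = self.frequencies[i, j]
        if f == 0:
            return np.zeros_like(t) if deriv else np.ones_like(t)
        w = 2.0 * np.pi * f / self.shape[j]
        arg = w * t + self.phases[i, j]
        return w * np.cos(arg) if deriv else np.sin(arg)

    def displacement(self, points: np.ndarray) -> np.ndarray:
        """d at continuous points, shape (L, 3) -> (L, 3)."""
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        out = np.empty_like(pts)
        for i in range(3):
            prod = np.full(pts.shape[0], self.amplitudes[i])
            for j in range(3):
                prod = prod * self._factor(i, j, pts[:, j], deriv=False)
            out[:, i] = prod
        return out

    def jacobian_determinant(self, points: np.ndarray) -> np.ndarray:
        """Continuous det(I + grad d) at arbitrary points (closed-form partials)."""
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        J = np.tile(np.eye(3), (pts.shape[0], 1, 1))
        for i in range(3):
            for j in range(3):
                term = np.full(pts.shape[0], self.amplitudes[i])
                for k in range(3):
                    term = term * self._factor(i, k, pts[:, k], deriv=(k == j))
                J[:, i, j] += term
        return np.linalg.det(J)


def make_sinusoid_field(
    amplitudes: Sequence[float],
    frequencies: np.ndarray,
    domain: GridDomain,
    phases: Optional[np.ndarray] = None,
) -> Tuple[DisplacementField, SinusoidField]:
    """Smooth separable-sinusoid field with an analytic Jacobian evaluator.

    Rejected (with the violating voxel) when the discrete determinant is not
    strictly positive — amplitude times frequency must stay small enough.
    """
    amps = np.asarray(amplitudes, dtype=float).reshape(3)
    freqs = np.asarray(frequencies, dtype=float).reshape(3, 3)
    ph = np.zeros((3, 3)) if phases is None else np.asarray(phases, dtype=float).reshape(3, 3)
    model = SinusoidField(amps, freqs, ph, domain.shape)
    X = np.stack(_coords(domain)).reshape(3, -1).T
    data = model.displacement(X).T.reshape(3, *domain.shape)
    fld = DisplacementField(domain, data)
    _check_positive_det(fld, "sinusoid field")
    return fld, model


def make_smooth_random_field(
    domain: GridDomain, amplitude: float, smooth_sigma: float, seed: int
) -> DisplacementField:
    """Filtered-noise field: seeded white noise, Gaussian-smoothed, rescaled.

    ``amplitude`` is the maximum absolute displacement (voxels) per component
    after smoothing; small amplitudes keep the field diffeomorphic.
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    data = np.empty((3, *domain.shape))
    for c in range(3):
        noise = rng.standard_normal(domain.shape)
        sm = gaussian_filter(noise, smooth_sigma, mode="nearest")
        peak = np.max(np.abs(sm))
        data[c] = amplitude * sm / peak if peak > 0 else sm
    fld = DisplacementField(domain, data)
    _check_positive_det(fld, "smooth random field")
    return fld


def make_contraction_case(
    domain: GridDomain,
    mean_jacobian: float = 0.79,
    seed: int = 0,
) -> Tuple[DisplacementField, ScalarImage]:
    """A contraction-flavoured ground-truth field and its discrete Jacobian image.

    Emulates exhale-to-inhale lung motion at desk scale: a uniform volumetric
    contraction (mean Jacobian ~ ``mean_jacobian``) overlaid with seeded
    sinusoid modes so the Jacobian image has genuine spatial structure — some
    voxels above 1 and some below 0.5, which the bound constraints then clip.
    """
    s = mean_jacobian ** (1.0 / 3.0)
    affine, _ = make_affine_field(np.eye(3) * s, np.zeros(3), domain)
    rng = np.random.default_rng(seed)
    freqs = np.zeros((3, 3))
    for i in range(3):
        freqs[i, i] = 1.0
        freqs[i, (i + 1) % 3] = 1.0
    phases = rng.uniform(0, 2 * np.pi, size=(3, 3))
    amps = np.array([0.55, 0.50, 0.30]) * np.asarray(domain.shape) / 24.0
    sin_fld, _ = make_sinusoid_field(amps, freqs, domain, phases)
    fld = DisplacementField(domain, affine.data + sin_fld.data)
    _check_positive_det(fld, "contraction case")
    det = det3(forward_jacobian(fld).entries)
    return fld, ScalarImage(domain, det)


def make_functional_image(
    jac: ScalarImage, rho: float, seed: int, mask: Optional[np.ndarray] = None
) -> ScalarImage:
    """Functional image g with sample Pearson corr(g, jac) = rho exactly.

    Built by Gram-Schmidt mixing: seeded smooth noise is projected orthogonal
    to the standardized Jacobian values over the mask and the two unit
    vectors are combined as rho * z + sqrt(1 - rho^2) * w.  Outside the mask
    g is zero.
    """
    if not (-1.0 <= rho <= 1.0):
        raise ValueError(f"rho must lie in [-1, 1], got {rho}")
    om = jac.domain.omega() if mask is None else np.asarray(mask, dtype=bool)
    vals = jac.values[om]
    z = vals - vals.mean()
    zn = np.linalg.norm(z)
    if zn == 0:
        raise ValueError("Jacobian image constant on the mask; correlation undefined")
    z /= zn

    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    noise = gaussian_filter(rng.standard_normal(jac.domain.shape), 1.5, mode="nearest")
    w = noise[om]
    w = w - w.mean()
    w = w - (w @ z) * z
    wn = np.linalg.norm(w)
    if wn == 0:  # pragma: no cover - measure-zero with continuous noise
        raise ValueError("degenerate noise draw; change the seed")
    w /= wn

    g = np.zeros(jac.domain.shape)
    g[om] = rho * z + np.sqrt(max(0.0, 1.0 - rho * rho)) * w
    return ScalarImage(jac.domain, g)


def sample_fidelity(
    fld: DisplacementField, fraction: float, noise_sigma: float, seed: int
) -> FidelityData:
    """Noisy displacement estimates y_i = d(x_i) + N(0, sigma^2) on a seeded subset of Omega."""
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    om = fld.domain.omega()
    flat = np.flatnonzero(om.ravel())
    if flat.size == 0:
        raise ValueError("Omega is empty")
    rng = np.random.default_rng(seed)
    m = max(1, int(round(fraction * flat.size)))
    chosen = np.sort(rng.choice(flat, size=m, replace=False))
    idx = np.stack(np.unravel_index(chosen, fld.domain.shape), axis=1)
    vals = fld.data.reshape(3, -1)[:, chosen].T.copy()
    if noise_sigma > 0:
        vals += rng.normal(0.0, noise_sigma, size=vals.shape)
    return FidelityData(idx, vals)


def make_landmarks(
    fld: DisplacementField, count: int, seed: int, noise_sigma: float = 0.0
) -> LandmarkSet:
    """Landmark pairs consistent with the field: target = phi(reference) (+ noise).

    Reference points are sampled continuously inside the grid; optional
    Gaussian annotation noise (voxel units) is added to the targets.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    n = np.asarray(fld.domain.shape, dtype=float)
    ref = rng.uniform(0.0, n - 1.0, size=(count, 3))
    tgt = map_points(fld, ref)
    if noise_sigma > 0:
        tgt = tgt + rng.normal(0.0, noise_sigma, size=tgt.shape)
    return LandmarkSet(ref, tgt, fld.domain.spacing)
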