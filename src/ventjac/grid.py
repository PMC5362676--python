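"""Core grid types and Jacobian/ventilation operators on displacement fields.

All displacement arithmetic is carried out in *voxel units*: component ``c``
of a displacement field moves material along array axis ``c``, measured in
multiples of the voxel spacing along that axis.  Physical spacing (mm per
voxel) enters only when landmark errors are reported in millimetres.

The ventilation metric at a voxel is the forward-difference Jacobian
determinant minus one, i.e. the estimated fractional (specific) volume change
of the voxel under the transformation ``phi(x) = x + d(x)``.  Forward
differences are one-sided: where a forward neighbor would fall outside the
grid the neighboring value is replicated, which makes the difference zero and
the corresponding Jacobian row/column entry revert to the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "GridDomain",
    "DisplacementField",
    "ScalarImage",
    "JacobianMatrixField",
    "forward_difference",
    "forward_jacobian",
    "jacobian_determinant",
    "det3",
    "cofactor3",
    "ventilation_image",
    "displacement_gradient",
    "gaussian_smooth",
]


class InvalidInputError(ValueError):
    """Raised when a field/image fails basic validity checks."""


@dataclass(frozen=True)
class GridDomain:
    """A regular 3-D voxel grid with optional region-of-interest mask.

    Parameters
    ----------
    shape
        Grid extents ``(n1, n2, n3)``; each must be >= 2 so that forward
        differences exist along every axis.
    spacing
        Voxel size in mm along each axis; strictly positive.
    mask
        Optional boolean volume marking the region of interest Omega.  When
        absent, Omega is the whole grid.
    """

    shape: Tuple[int, int, int]
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        if len(shape) != 3 or any(n < 2 for n in shape):
            raise InvalidInputError(f"grid shape must be three extents >= 2, got {shape}")
        if len(spacing) != 3 or any(not np.isfinite(s) or s <= 0 for s in spacing):
            raise InvalidInputError(f"spacing must be three positive lengths, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != shape:
                raise InvalidInputError("mask shape does not match grid shape")
            if not m.any():
                raise InvalidInputError("mask has no voxels in Omega")
            object.__setattr__(self, "mask", m)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def omega(self) -> np.ndarray:
        """Boolean volume of the region of interest Omega."""
        if self.mask is not None:
            return self.mask
        return np.ones(self.shape, dtype=bool)

    def interior(self) -> np.ndarray:
        """Voxels whose three forward neighbors all lie inside Omega.

        These are the voxels where the forward-difference Jacobian uses no
        boundary replication; Jacobian equality constraints are enforced only
        here.
        """
        om = self.omega()
        ok = om.copy()
        for ax in range(3):
            nb = np.zeros_like(om)
            sl_dst = [slice(None)] * 3
            sl_src = [slice(None)] * 3
            sl_dst[ax] = slice(0, -1)
            sl_src[ax] = slice(1, None)
            nb[tuple(sl_dst)] = om[tuple(sl_src)]
            ok &= nb
        return ok


def _check_finite(arr: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{what} contains non-finite values")


@dataclass(frozen=True)
class DisplacementField:
    """Three-component displacement field d(x) on a grid, in voxel units.

    ``data`` has shape ``(3, n1, n2, n3)``; ``data[c]`` is the displacement
    along axis ``c``.
    """

    domain: GridDomain
    data: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.shape != (3, *self.domain.shape):
            raise InvalidInputError(
                f"field data shape {d.shape} does not match (3, *{self.domain.shape})"
            )
        _check_finite(d, "displacement field")
        object.__setattr__(self, "data", d)

    @classmethod
    def zeros(cls, domain: GridDomain) -> "DisplacementField":
        return cls(domain, np.zeros((3, *domain.shape)))

    def component(self, c: int) -> np.ndarray:
        return self.data[c]

    def copy(self) -> "DisplacementField":
        return DisplacementField(self.domain, self.data.copy())


@dataclass(frozen=True)
class ScalarImage:
    """Scalar volume on a grid (Jacobian images, constraints, masks, ...)."""

    domain: GridDomain
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.domain.shape:
            raise InvalidInputError(
                f"image shape {v.shape} does not match grid {self.domain.shape}"
            )
        _check_finite(v, "scalar image")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class JacobianMatrixField:
    """Per-voxel 3x3 forward-difference Jacobian; ``entries[i, j]`` is a volume."""

    domain: GridDomain
    entries: np.ndarray  # shape (3, 3, n1, n2, n3)

    def __post_init__(self):
        e = np.asarray(self.entries, dtype=float)
        if e.shape != (3, 3, *self.domain.shape):
            raise InvalidInputError("Jacobian entries must have shape (3, 3, *grid)")
        _check_finite(e, "Jacobian entries")
        object.__setattr__(self, "entries", e)


# ---------------------------------------------------------------------------
# Forward differences and the Jacobian
# ---------------------------------------------------------------------------

def forward_difference(volume: np.ndarray, axis: int) -> np.ndarray:
    """One-sided difference v(x + e_axis) - v(x) with boundary replication.

    The last slice along ``axis`` has no forward neighbor; replication makes
    its difference zero.
    """
    out = np.zeros_like(volume, dtype=float)
    dst = [slice(None)] * 3
    a = [slice(None)] * 3
    b = [slice(None)] * 3
    dst[axis] = slice(0, -1)
    a[axis] = slice(1, None)
    b[axis] = slice(0, -1)
    out[tuple(dst)] = volume[tuple(a)] - volume[tuple(b)]
    return out


def forward_jacobian(fld: DisplacementField) -> JacobianMatrixField:
    """Forward-difference Jacobian J~(x_k; d) of phi = x + d at every voxel.

    Entry (i, j) = delta_ij + d^(i)(x_k + e_j) - d^(i)(x_k).  Exact when the
    transformation is affine.
    """
    n = fld.domain.shape
    entries = np.empty((3, 3, *n))
    for i in range(3):
        for j in range(3):
            entries[i, j] = forward_difference(fld.data[i], j)
            if i == j:
                entries[i, j] += 1.0
    return JacobianMatrixField(fld.domain, entries)


def det3(entries: np.ndarray) -> np.ndarray:
    """Determinant of a field of 3x3 matrices, shape (3, 3, ...) -> (...).

    Explicit cofactor expansion along the first row; elementwise over the
    trailing grid axes.
    """
    a, b, c = entries[0, 0], entries[0, 1], entries[0, 2]
    d, e, f = entries[1, 0], entries[1, 1], entries[1, 2]
    g, h, i = entries[2, 0], entries[2, 1], entries[2, 2]
    return a * (e * i - f * h) - b * (d * i - f * g) + c * (d * h - e * g)


def cofactor3(entries: np.ndarray) -> np.ndarray:
    """Cofactor matrices of a field of 3x3 matrices; d det / d J_ij = cof_ij."""
    a, b, c = entries[0, 0], entries[0, 1], entries[0, 2]
    d, e, f = entries[1, 0], entries[1, 1], entries[1, 2]
    g, h, i = entries[2, 0], entries[2, 1], entries[2, 2]
    cof = np.empty_like(entries)
    cof[0, 0] = e * i - f * h
    cof[0, 1] = -(d * i - f * g)
    cof[0, 2] = d * h - e * g
    cof[1, 0] = -(b * i - c * h)
    cof[1, 1] = a * i - c * g
    cof[1, 2] = -(a * h - b * g)
    cof[2, 0] = b * f - c * e
    cof[2, 1] = -(a * f - c * d)
    cof[2, 2] = a * e - b * d
    return cof


def jacobian_determinant(
    jac: JacobianMatrixField, subset: Optional[np.ndarray] = None, fill: float = np.nan
) -> ScalarImage:
    """Per-voxel determinant of the Jacobian matrix field.

    ``subset`` is an optional boolean volume; voxels outside it are set to
    ``fill`` (NaN by default).  NaN fills are permitted in the output image.
    """
    det = det3(jac.entries)
    if subset is not None:
        det = np.where(subset, det, fill)
    img = ScalarImage.__new__(ScalarImage)
    object.__setattr__(img, "domain", jac.domain)
    object.__setattr__(img, "values", np.asarray(det, dtype=float))
    return img


def ventilation_image(fld: DisplacementField) -> ScalarImage:
    """Ventilation metric V(x_k) = det(J~(x_k; d)) - 1 at every voxel."""
    det = det3(forward_jacobian(fld).entries)
    return ScalarImage(fld.domain, det - 1.0)


def displacement_gradient(
    fld: DisplacementField, component: int, voxel: Sequence[int]
) -> np.ndarray:
    """Discrete forward-difference gradient of component ``j`` at one voxel.

    Returns the 3-vector of differences d^(j)(x_k + e_a) - d^(j)(x_k) for
    a = 1..3, with boundary replication.
    """
    i1, i2, i3 = (int(v) for v in voxel)
    n = fld.domain.shape
    if not (0 <= i1 < n[0] and 0 <= i2 < n[1] and 0 <= i3 < n[2]):
        raise IndexError(f"voxel {(i1, i2, i3)} outside grid {n}")
    d = fld.data[component]
    out = np.zeros(3)
    idx = (i1, i2, i3)
    for ax in range(3):
        if idx[ax] + 1 < n[ax]:
            nb = list(idx)
            nb[ax] += 1
            out[ax] = d[tuple(nb)] - d[idx]
    return out


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

_GAUSS_TRUNCATE = 4.0  # kernel support in multiples of sigma


def gaussian_smooth(
    image: ScalarImage, sigma: float, mask: Optional[np.ndarray] = None
) -> ScalarImage:
    """Mask-renormalized Gaussian smoothing, G_sigma * image.

    The kernel is truncated at 4 sigma and renormalized so a constant image
    stays constant.  With a mask (defaulting to the domain's Omega when one
    is set), weights falling outside Omega are excluded and the kernel is
    re-normalized over the remaining weights, so values inside Omega never
    leak mass to, or draw values from, the outside.  ``sigma = 0`` is the
    identity.
    """
    if not np.isfinite(sigma) or sigma < 0:
        raise InvalidInputError(f"sigma must be >= 0, got {sigma}")
    if mask is None:
        mask = image.domain.mask
    if sigma == 0:
        return ScalarImage(image.domain, image.values.copy())
    if mask is None:
        num = ndimage.gaussian_filter(
            image.values, sigma, mode="constant", cval=0.0, truncate=_GAUSS_TRUNCATE
        )
        den = ndimage.gaussian_filter(
            np.ones(image.domain.shape), sigma, mode="constant", cval=0.0,
            truncate=_GAUSS_TRUNCATE,
        )
        return ScalarImage(image.domain, num / den)
    m = np.asarray(mask, dtype=float)
    num = ndimage.gaussian_filter(
        image.values * m, sigma, mode="constant", cval=0.0, truncate=_GAUSS_TRUNCATE
    )
    den = ndimage.gaussian_filter(m, sigma, mode="constant", cval=0.0, truncate=_GAUSS_TRUNCATE)
    out = image.values.copy()
    inside = m > 0
    out[inside] = num[inside] / den[inside]
    return ScalarImage(image.domain, out)
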