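"""Single-voxel perturbation analysis of the ventilation metric.

Perturbing the displacement vector at one voxel, d(x_k) -> d(x_k) - h, adds
h to every forward-difference entry that contains -d(x_k); in matrix form the
Jacobian becomes J~ + h 1^T (a rank-one update).  The induced change in the
ventilation metric obeys

    |V_h - V~(x_k)| <= (3 sqrt(3) / 2) ||h|| * max_i prod_{j != i} (1 + ||grad d^(j)(x_k)||),

with the discrete forward-difference gradients and Euclidean norms.  With a
perfectly rigid field (all gradients zero) the bound is about 2.6 ||h||:
changing a single displacement by one voxel can swing the metric by 1.0, the
difference between zero volume change and a doubling of the voxel volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .grid import DisplacementField, det3, displacement_gradient, forward_jacobian

__all__ = [
    "Perturbation",
    "jacobian_matrix_at",
    "perturbed_metric",
    "perturbation_bound",
    "empirical_max_change",
]

_BOUND_COEFF = 3.0 * math.sqrt(3.0) / 2.0


@dataclass(frozen=True)
class Perturbation:
    """A perturbation h (voxel units) applied to the displacement at one voxel."""

    voxel: Tuple[int, int, int]
    h: np.ndarray

    def __post_init__(self):
        h = np.asarray(self.h, dtype=float).reshape(3)
        if not np.all(np.isfinite(h)):
            raise ValueError("perturbation vector must be finite")
        object.__setattr__(self, "h", h)
        object.__setattr__(self, "voxel", tuple(int(v) for v in self.voxel))


def _check_voxel(fld: DisplacementField, voxel: Sequence[int]) -> Tuple[int, int, int]:
    v = tuple(int(x) for x in voxel)
    n = fld.domain.shape
    if not all(0 <= v[a] < n[a] for a in range(3)):
        raise IndexError(f"voxel {v} outside grid {n}")
    return v


def jacobian_matrix_at(fld: DisplacementField, voxel: Sequence[int]) -> np.ndarray:
    """The 3x3 forward-difference Jacobian at a single voxel."""
    v = _check_voxel(fld, voxel)
    n = fld.domain.shape
    J = np.eye(3)
    for i in range(3):
        for j in range(3):
            if v[j] + 1 < n[j]:
                nb = list(v)
                nb[j] += 1
                J[i, j] += fld.data[i][tuple(nb)] - fld.data[i][v]
    return J


def perturbed_metric(fld: DisplacementField, pert: Perturbation) -> float:
    """Ventilation metric after replacing d(x_k) with d(x_k) - h.

    Computed as det(J~ + h 1^T) - 1; identical to editing the field in place
    and re-evaluating the metric at x_k.
    """
    J = jacobian_matrix_at(fld, pert.voxel)
    return float(np.linalg.det(J + np.outer(pert.h, np.ones(3))) - 1.0)


def perturbation_bound(
    fld: DisplacementField, voxel: Sequence[int], h_norm: float
) -> float:
    """Theoretical bound on |V_h - V~(x_k)| for any perturbation of norm ``h_norm``."""
    if not np.isfinite(h_norm) or h_norm < 0:
        raise ValueError(f"h_norm must be >= 0, got {h_norm}")
    v = _check_voxel(fld, voxel)
    gnorm = [
        float(np.linalg.norm(displacement_gradient(fld, j, v))) for j in range(3)
    ]
    best = 0.0
    for i in range(3):
        prod = 1.0
        for j in range(3):
            if j != i:
                prod *= 1.0 + gnorm[j]
        best = max(best, prod)
    return _BOUND_COEFF * h_norm * best


def empirical_max_change(
    fld: DisplacementField,
    voxel: Sequence[int],
    h_norm: float,
    n_samples: int,
    seed: int,
) -> Tuple[float, np.ndarray]:
    """Monte-Carlo maximum of |V_h - V~| over directions of norm ``h_norm``.

    Samples ``n_samples`` directions uniformly on the sphere (normalized
    standard normals) and always includes the six +/- axis directions.
    Returns the largest observed change and the h that attains it.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not (h_norm > 0):
        raise ValueError("h_norm must be > 0")
    v = _check_voxel(fld, voxel)
    rng = np.random.default_rng(seed)
    dirs = rng.standard_normal((n_samples, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    axes = np.concatenate([np.eye(3), -np.eye(3)])
    hs = h_norm * np.concatenate([axes, dirs])

    J = jacobian_matrix_at(fld, v)
    base = float(np.linalg.det(J)) - 1.0
    # batched rank-one updates: J + h 1^T for every sampled h
    mats = J[None, :, :] + hs[:, :, None] * np.ones(3)[None, None, :]
    changes = np.abs(np.linalg.det(mats) - 1.0 - base)
    k = int(np.argmax(changes))
    return float(changes[k]), hs[k]
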