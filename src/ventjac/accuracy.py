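"""Landmark-based spatial accuracy of displacement fields, in millimetres.

A displacement field maps a reference-phase point p to phi(p) = p + d(p),
with d evaluated by trilinear interpolation at continuous positions (exact at
grid nodes).  The error of a landmark pair is the Euclidean distance in mm
between phi(reference) and the expert-annotated target position, after
scaling each axis by its voxel spacing.  Summary statistics use the
population standard deviation by default (switchable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .grid import DisplacementField, InvalidInputError

__all__ = ["LandmarkSet", "read_landmarks", "map_points", "landmark_error_stats"]


class LandmarkParseError(ValueError):
    """A landmark file row could not be parsed."""


@dataclass(frozen=True)
class LandmarkSet:
    """Paired reference/target landmark points in 0-based voxel coordinates."""

    reference: np.ndarray  # (L, 3) continuous voxel coordinates
    target: np.ndarray     # (L, 3)
    spacing: Tuple[float, float, float]

    def __post_init__(self):
        ref = np.asarray(self.reference, dtype=float).reshape(-1, 3)
        tgt = np.asarray(self.target, dtype=float).reshape(-1, 3)
        if ref.shape[0] != tgt.shape[0] or ref.shape[0] < 1:
            raise InvalidInputError("landmark lists must be equally long and non-empty")
        if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(tgt))):
            raise InvalidInputError("landmark coordinates must be finite")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise InvalidInputError("spacing must be three positive lengths")
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "target", tgt)
        object.__setattr__(self, "spacing", sp)

    def __len__(self) -> int:
        return int(self.reference.shape[0])


def read_landmarks(path, index_base: int = 1) -> np.ndarray:
    """Parse a whitespace-delimited landmark text file (one x1 x2 x3 row per point).

    ``index_base`` is the file's indexing origin (dir-lab files are 1-based);
    coordinates are converted to the package's 0-based convention.
    """
    points = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            parts = s.split()
            if len(parts) != 3:
                raise LandmarkParseError(
                    f"{path}:{lineno}: expected three coordinates, got {len(parts)}"
                )
            try:
                points.append([float(p) for p in parts])
            except ValueError as exc:
                raise LandmarkParseError(f"{path}:{lineno}: {exc}") from exc
    if not points:
        raise LandmarkParseError(f"{path}: no landmark rows found")
    return np.asarray(points, dtype=float) - float(index_base)


def map_points(fld: DisplacementField, points: np.ndarray) -> np.ndarray:
    """phi(p) = p + d(p) with d trilinearly interpolated at continuous points."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    n = np.asarray(fld.domain.shape, dtype=float)
    if np.any(pts < -1e-9) or np.any(pts > n - 1 + 1e-9):
        bad = np.argwhere((pts < -1e-9) | (pts > n - 1 + 1e-9))
        raise IndexError(f"{len(set(bad[:, 0]))} landmark(s) outside the grid")
    coords = pts.T
    disp = np.stack(
        [map_coordinates(fld.data[c], coords, order=1, mode="nearest") for c in range(3)],
        axis=1,
    )
    return pts + disp


def landmark_error_stats(
    fld: DisplacementField, landmarks: LandmarkSet, sample_std: bool = False
):
    """Per-landmark mm error ||(phi(ref) - target) * spacing|| and summaries.

    Returns ``(mean_mm, std_mm, max_mm, table)`` where ``table`` is a
    DataFrame with one row per landmark.  ``sample_std=True`` switches the
    standard deviation from the population (divide by n) to the sample
    (divide by n-1) convention.
    """
    mapped = map_points(fld, landmarks.reference)
    diff_mm = (mapped - landmarks.target) * np.asarray(landmarks.spacing)
    err = np.linalg.norm(diff_mm, axis=1)
    table = pd.DataFrame(
        {
            "ref_x1": landmarks.reference[:, 0],
            "ref_x2": landmarks.reference[:, 1],
            "ref_x3": landmarks.reference[:, 2],
            "mapped_x1": mapped[:, 0],
            "mapped_x2": mapped[:, 1],
            "mapped_x3": mapped[:, 2],
            "error_mm": err,
        }
    )
    ddof = 1 if sample_std else 0
    return float(err.mean()), float(err.std(ddof=ddof)), float(err.max()), table
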