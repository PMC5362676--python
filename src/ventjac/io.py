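"""File I/O: MetaImage / NIfTI volumes, fidelity CSVs, configs, reports.

Internal convention: arrays are indexed ``(x1, x2, x3)`` and displacement
component ``c`` moves along axis ``c`` in voxel units.  SimpleITK returns
arrays with the slice axis first, so volumes are transposed on read/write;
vector fields stored in mm are converted to voxel units by dividing each
component by its axis spacing (``units="mm"``).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .grid import DisplacementField, GridDomain, InvalidInputError, ScalarImage
from .solver import FidelityData, SolverOptions

__all__ = [
    "read_vector_image",
    "write_vector_image",
    "read_scalar_image",
    "write_scalar_image",
    "read_fidelity_csv",
    "write_fidelity_csv",
    "ExperimentConfig",
]


def _domain_from_sitk(img: sitk.Image, shape: Tuple[int, int, int]) -> GridDomain:
    return GridDomain(shape, tuple(float(s) for s in img.GetSpacing()))


def read_vector_image(path, units: str = "voxels") -> DisplacementField:
    """Read a 3-component MetaImage/NIfTI volume as a displacement field.

    ``units="mm"`` divides component c by spacing[c] on read (the file's
    spacing metadata is then required to be positive).
    """
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # (n3, n2, n1, 3)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise InvalidInputError(
            f"{path}: expected a 3-component vector volume, got array shape {arr.shape}"
        )
    data = np.transpose(arr, (3, 2, 1, 0)).astype(float)  # (3, n1, n2, n3)
    domain = _domain_from_sitk(img, data.shape[1:])
    if units == "mm":
        for c in range(3):
            data[c] /= domain.spacing[c]
    elif units != "voxels":
        raise ValueError(f"units must be 'voxels' or 'mm', got {units!r}")
    return DisplacementField(domain, data)


def write_vector_image(path, fld: DisplacementField, units: str = "voxels") -> None:
    """Write a displacement field as a 3-component volume with spacing metadata."""
    data = fld.data.copy()
    if units == "mm":
        for c in range(3):
            data[c] *= fld.domain.spacing[c]
    elif units != "voxels":
        raise ValueError(f"units must be 'voxels' or 'mm', got {units!r}")
    arr = np.transpose(data, (3, 2, 1, 0))  # (n3, n2, n1, 3)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr), isVector=True)
    img.SetSpacing(tuple(float(s) for s in fld.domain.spacing))
    sitk.WriteImage(img, str(path))


def read_scalar_image(path, domain: Optional[GridDomain] = None) -> ScalarImage:
    """Read a scalar MetaImage/NIfTI volume; optionally check it matches ``domain``."""
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim != 3:
        raise InvalidInputError(f"{path}: expected a scalar 3-D volume, got shape {arr.shape}")
    vals = np.transpose(arr, (2, 1, 0)).astype(float)
    dom = _domain_from_sitk(img, vals.shape)
    if domain is not None:
        if tuple(domain.shape) != vals.shape:
            raise InvalidInputError(
                f"{path}: shape {vals.shape} does not match expected {domain.shape}"
            )
        dom = domain
    return ScalarImage(dom, vals)


def write_scalar_image(path, image: ScalarImage) -> None:
    arr = np.transpose(image.values, (2, 1, 0))
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr))
    img.SetSpacing(tuple(float(s) for s in image.domain.spacing))
    sitk.WriteImage(img, str(path))


def read_fidelity_csv(path) -> FidelityData:
    """CSV with columns i1,i2,i3,y1,y2,y3 (0-based voxel indices, voxel units)."""
    df = pd.read_csv(path)
    need = ["i1", "i2", "i3", "y1", "y2", "y3"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing fidelity columns {missing}")
    return FidelityData(df[["i1", "i2", "i3"]].to_numpy(), df[["y1", "y2", "y3"]].to_numpy())


def write_fidelity_csv(path, fidelity: FidelityData) -> None:
    pd.DataFrame(
        {
            "i1": fidelity.indices[:, 0],
            "i2": fidelity.indices[:, 1],
            "i3": fidelity.indices[:, 2],
            "y1": fidelity.values[:, 0],
            "y2": fidelity.values[:, 1],
            "y3": fidelity.values[:, 2],
        }
    ).to_csv(path, index=False)


@dataclass
class ExperimentConfig:
    """Configuration of one constrained-ventilation experiment.

    ``constraint_mode`` is one of ``smooth``, ``bounds``, ``correlation`` or
    ``identity`` (target = the unconstrained solution's own Jacobian image).
    File paths may be omitted when the experiment is driven from in-memory
    synthetic inputs.
    """

    constraint_mode: str = "bounds"
    LB: float = 0.5
    UB: float = 1.0
    sigma: float = 1.0
    functional_image: Optional[str] = None
    fidelity_file: Optional[str] = None
    field_file: Optional[str] = None
    landmarks_reference: Optional[str] = None
    landmarks_target: Optional[str] = None
    landmark_index_base: int = 1
    output_dir: str = "."
    seed: int = 0
    solver: SolverOptions = dc_field(default_factory=SolverOptions)

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        solver = SolverOptions(**raw.pop("solver", {}))
        return cls(solver=solver, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d
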