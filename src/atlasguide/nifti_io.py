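"""NIfTI-1 reading and writing for all volume types.

Only axis-aligned affines (positive diagonal, no rotation or shear) are
accepted: the registration core assumes axis-aligned grids in mm, and a
silent reorientation would corrupt world geometry.  Oblique inputs must be
resampled externally.  Displacement fields are stored as 4D NIfTI with the
vector dimension last, in mm.
"""

from __future__ import annotations

import numpy as np
import nibabel as nib

from .image_model import (
    DisplacementField,
    ImageGrid,
    LabelVolume,
    MaskVolume,
    ScalarVolume,
)

__all__ = ["read_volume", "write_volume", "read_displacement_field", "write_displacement_field"]


def _grid_from_affine(affine: np.ndarray, shape) -> ImageGrid:
    lin = affine[:3, :3]
    off_diag = lin - np.diag(np.diag(lin))
    if np.abs(off_diag).max() > 1e-6 * max(1.0, np.abs(lin).max()):
        raise ValueError(
            "only axis-aligned NIfTI affines are supported; "
            "resample oblique/sheared volumes externally"
        )
    spacing = np.diag(lin)
    if np.any(spacing <= 0):
        raise ValueError("affine must have a positive diagonal (RAS-aligned, no flips)")
    return ImageGrid(tuple(shape[:3]), tuple(spacing), tuple(affine[:3, 3]))


def _affine_from_grid(grid: ImageGrid) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(grid.spacing)
    affine[:3, 3] = grid.origin
    return affine


def read_volume(path, kind: str = "scalar"):
    """Read a NIfTI volume as a ``scalar``, ``mask`` or ``label`` volume.

    Mask files must be strictly binary and label files integer-valued;
    anything else is rejected rather than coerced.
    """
    img = nib.load(str(path))
    grid = _grid_from_affine(img.affine, img.shape)
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    if kind == "scalar":
        return ScalarVolume(grid, data.astype(float))
    if kind == "mask":
        if not np.isin(data, (0, 1)).all():
            raise ValueError(f"{path} contains non-binary values; cannot read as mask")
        return MaskVolume(grid, data.astype(np.uint8))
    if kind == "label":
        return LabelVolume(grid, data)
    raise ValueError(f"unknown volume kind {kind!r}")


def write_volume(volume, path) -> None:
    """Write a volume to NIfTI-1, preserving spacing and origin exactly."""
    if isinstance(volume, LabelVolume):
        data = volume.values.astype(np.int32)
    elif isinstance(volume, MaskVolume):
        data = volume.values.astype(np.uint8)
    else:
        data = volume.values.astype(np.float64)
    img = nib.Nifti1Image(data, _affine_from_grid(volume.grid))
    nib.save(img, str(path))


def read_displacement_field(path) -> DisplacementField:
    img = nib.load(str(path))
    grid = _grid_from_affine(img.affine, img.shape)
    data = np.asarray(img.dataobj)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError("displacement field must be 4D with a trailing vector dimension")
    return DisplacementField(grid, data.astype(float))


def write_displacement_field(field: DisplacementField, path) -> None:
    img = nib.Nifti1Image(field.u.astype(np.float64), _affine_from_grid(field.grid))
    nib.save(img, str(path))
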