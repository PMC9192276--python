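"""Volume and contour-set file I/O.

Volumes travel as NIfTI (.nii / .nii.gz) with the affine carrying spacing on
its diagonal and the origin in its translation column; tri-state fields are
stored the same way as int8 label volumes with values {−1, 0, 1}.

Contour sets use a small JSON schema::

    {"slice_axis": 2,
     "slices": [{"index": 12, "polygons": [[[x, y], ...], ...]}, ...]}

with polygon vertices in world mm of the two in-plane axes and implicit
closure (first vertex not repeated).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import ContourSet, SliceContours, TriStateField, VoxelGrid
from .errors import InvalidInputError

__all__ = [
    "save_volume", "load_volume", "save_field", "load_field",
    "save_contours", "load_contours",
]


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def save_volume(grid: VoxelGrid, path) -> None:
    """Write a scalar volume as NIfTI."""
    img = nib.Nifti1Image(grid.values.astype(np.float32), _affine(grid.spacing, grid.origin))
    nib.save(img, str(path))


def load_volume(path) -> VoxelGrid:
    """Read a NIfTI scalar volume (axis-aligned affine required)."""
    img = nib.load(str(path))
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
        raise InvalidInputError(f"{path}: only axis-aligned affines are supported")
    spacing = np.diag(aff[:3, :3]).copy()
    if (spacing <= 0).any():
        raise InvalidInputError(f"{path}: affine has non-positive spacing {spacing}")
    return VoxelGrid(values=np.asarray(img.dataobj, dtype=np.float64),
                     spacing=spacing, origin=aff[:3, 3].copy())


def save_field(field: TriStateField, path) -> None:
    """Write a tri-state field as an int8 NIfTI label volume."""
    img = nib.Nifti1Image(field.labels.astype(np.int8), _affine(field.spacing, field.origin))
    nib.save(img, str(path))


def load_field(path) -> TriStateField:
    """Read a tri-state label volume; values must be in {−1, 0, 1}."""
    grid = load_volume(path)
    labels = grid.values
    if not np.isin(labels, (-1.0, 0.0, 1.0)).all():
        raise InvalidInputError(f"{path}: label volume contains values outside {{-1, 0, 1}}")
    return TriStateField(labels=labels.astype(np.int8), spacing=grid.spacing, origin=grid.origin)


def save_contours(contours: ContourSet, path) -> None:
    doc = {
        "slice_axis": int(contours.slice_axis),
        "slices": [
            {"index": int(s.index),
             "polygons": [p.tolist() for p in s.polygons]}
            for s in contours.slices
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_contours(path) -> ContourSet:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise InvalidInputError(f"{path}: not valid JSON ({exc})") from exc
    try:
        slices = [
            SliceContours(index=int(s["index"]),
                          polygons=[np.asarray(p, dtype=np.float64) for p in s["polygons"]])
            for s in doc["slices"]
        ]
        return ContourSet(slice_axis=int(doc["slice_axis"]), slices=slices)
    except (KeyError, TypeError) as exc:
        raise InvalidInputError(f"{path}: malformed contour document ({exc})") from exc
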