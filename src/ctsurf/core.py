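"""Core data containers shared across the pipeline.

The pipeline moves data through four containers:

``VoxelGrid``
    an axis-aligned scalar volume sampled on a regular grid — the digital
    stand-in for a stack of CT slices.  Voxel centres sit at integer indices;
    the world position of index ``(i, j, k)`` is ``origin + index * spacing``.

``ContourSet``
    per-slice closed polygons (the contour lines L1..Ln drawn on each slice)
    in world millimetre coordinates of the two in-plane axes.

``TriStateField``
    the tri-state voxel function f(a, b, c) with values −1 (outside all
    contours), 0 (on a contour) and +1 (inside), on the same grid geometry.

``TriMesh``
    an indexed triangle mesh in world coordinates, optionally carrying unit
    vertex normals — the reconstruction output and the decimation substrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidInputError

__all__ = ["VoxelGrid", "ContourSet", "SliceContours", "TriStateField", "TriMesh"]


def _as_triple(x, name: str, dtype=float) -> np.ndarray:
    arr = np.asarray(x, dtype=dtype).reshape(-1)
    if arr.size != 3:
        raise InvalidInputError(f"{name} must have exactly 3 components, got {arr.size}")
    return arr


@dataclass
class VoxelGrid:
    """Scalar volume on a regular axis-aligned grid.

    Parameters
    ----------
    values : (nx, ny, nz) ndarray
        Scalar sample at each voxel centre.
    spacing : length-3 sequence, mm
        Voxel spacing along each axis; all components strictly positive.
    origin : length-3 sequence, mm
        World coordinate of the voxel at index (0, 0, 0).
    """

    values: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise InvalidInputError(f"values must be 3-D, got ndim={self.values.ndim}")
        if any(d < 2 for d in self.values.shape):
            raise InvalidInputError(f"all dims must be >= 2, got {self.values.shape}")
        self.spacing = _as_triple(self.spacing, "spacing")
        if not np.all(self.spacing > 0):
            raise InvalidInputError(f"spacing must be positive, got {self.spacing}")
        self.origin = _as_triple(self.origin, "origin")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def world(self, index) -> np.ndarray:
        """World coordinate of a (possibly fractional) grid index."""
        return self.origin + np.asarray(index, dtype=float) * self.spacing


@dataclass
class SliceContours:
    """Closed polygons on one slice.

    Polygons are (n, 2) arrays of in-plane world coordinates (mm), implicit
    closure (the first vertex is not repeated at the end), at least 3 vertices.
    """

    index: int
    polygons: list[np.ndarray]

    def __post_init__(self):
        cleaned = []
        for p in self.polygons:
            p = np.asarray(p, dtype=np.float64)
            if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 3:
                raise InvalidInputError(
                    f"polygon on slice {self.index} must be (n>=3, 2), got {p.shape}")
            if np.allclose(p[0], p[-1]):
                p = p[:-1]
                if p.shape[0] < 3:
                    raise InvalidInputError(
                        f"degenerate polygon on slice {self.index} after closure removal")
            cleaned.append(p)
        self.polygons = cleaned


@dataclass
class ContourSet:
    """Per-slice contour polygons, ordered by slice index.

    ``slice_axis`` names the axis the slices are perpendicular to (2 = axial,
    the CT convention).  Polygon coordinates are world mm along the two
    remaining axes in ascending axis order.
    """

    slice_axis: int
    slices: list[SliceContours]

    def __post_init__(self):
        if self.slice_axis not in (0, 1, 2):
            raise InvalidInputError(f"slice_axis must be 0, 1 or 2, got {self.slice_axis}")
        self.slices = sorted(self.slices, key=lambda s: s.index)

    @property
    def inplane_axes(self) -> tuple[int, int]:
        return tuple(a for a in (0, 1, 2) if a != self.slice_axis)

    def polygons_by_slice(self) -> dict[int, list[np.ndarray]]:
        return {s.index: s.polygons for s in self.slices}


@dataclass
class TriStateField:
    """The tri-state voxel function on a regular grid.

    ``labels`` holds f(a, b, c) ∈ {−1, 0, +1} per voxel: −1 outside all
    contour lines of the voxel's slice, 0 on a contour line, +1 inside.
    """

    labels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise InvalidInputError(f"labels must be 3-D, got ndim={self.labels.ndim}")
        bad = ~np.isin(self.labels, (-1, 0, 1))
        if bad.any():
            raise InvalidInputError(
                f"labels must be in {{-1, 0, 1}}; {int(bad.sum())} offending voxels")
        self.labels = self.labels.astype(np.int8)
        self.spacing = _as_triple(self.spacing, "spacing")
        if not np.all(self.spacing > 0):
            raise InvalidInputError(f"spacing must be positive, got {self.spacing}")
        self.origin = _as_triple(self.origin, "origin")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.labels.shape

    def world(self, index) -> np.ndarray:
        return self.origin + np.asarray(index, dtype=float) * self.spacing


@dataclass
class TriMesh:
    """Indexed triangle mesh with optional unit vertex normals."""

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise InvalidInputError("face index out of range")
            f = self.faces
            if ((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])).any():
                raise InvalidInputError("face with repeated vertex index")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=np.float64).reshape(-1, 3)
            if len(self.normals) != len(self.vertices):
                raise InvalidInputError("normals count must match vertex count")
            norms = np.linalg.norm(self.normals, axis=1)
            if self.normals.size and not np.allclose(norms, 1.0, atol=1e-9):
                raise InvalidInputError("normals must be unit length")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges_unique(self) -> np.ndarray:
        """Unique undirected edges as a sorted (n, 2) int array."""
        if not self.faces.size:
            return np.empty((0, 2), dtype=np.int64)
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy(),
                       None if self.normals is None else self.normals.copy())
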