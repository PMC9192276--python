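"""Synthetic CT-like phantoms with known geometry.

Real inputs to this pipeline are segmented CT volumes of a hollow organ (a
bladder wall carrying one or more lesions).  No such volumes ship with the
package, so every downstream stage is exercised on phantoms: implicit solids
(positive inside, negative outside) with analytic or high-resolution numeric
ground truths for enclosed volume and surface area.  The phantoms are
deterministic given a seed, which makes them usable as test fixtures.

Three generators are provided:

* :func:`make_sphere` — closed-form ground truths; the primary calibration
  object for surface extraction and decimation.
* :func:`make_bladder_phantom` — an ellipsoidal shell (the bladder wall) with
  papillary lesions attached to the inner wall; ground truths are fine-grid
  numeric estimates and flagged approximate.
* :func:`make_blob_grid` — smooth random blob fields for stress-testing
  surface extraction against a reference implementation.

Sampling helpers convert a phantom to a :class:`~ctsurf.core.VoxelGrid`
(:func:`voxelize`) and a grid to per-slice iso-contour polygons
(:func:`contours_from_grid`), emulating the contour lines L1..Ln drawn on CT
slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import measure

from .core import ContourSet, SliceContours, VoxelGrid
from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "Phantom",
    "make_sphere",
    "make_bladder_phantom",
    "make_blob_grid",
    "voxelize",
    "contours_from_grid",
]


@dataclass
class Phantom:
    """An implicit solid with ground-truth volume and surface area.

    ``implicit_fn`` maps world coordinates (mm), shape (..., 3), to a signed
    scalar: positive inside the solid, negative outside, zero on the surface.
    ``analytic_volume`` (mm^3) and ``analytic_area`` (mm^2) are exact for
    closed-form shapes and high-resolution numeric estimates otherwise, in
    which case ``approximate`` is True.
    """

    implicit_fn: Callable[[np.ndarray], np.ndarray]
    analytic_volume: float
    analytic_area: float
    description: str = ""
    approximate: bool = False

    def __post_init__(self):
        if not self.analytic_volume > 0:
            raise InvalidParameterError(f"analytic_volume must be > 0, got {self.analytic_volume}")
        if not self.analytic_area > 0:
            raise InvalidParameterError(f"analytic_area must be > 0, got {self.analytic_area}")


def make_sphere(radius: float, center=(0.0, 0.0, 0.0)) -> Phantom:
    """Sphere phantom with closed-form ground truths.

    The implicit function is ``radius - |p - center|`` (a signed distance).
    """
    if not radius > 0:
        raise InvalidParameterError(f"radius must be > 0, got {radius}")
    c = np.asarray(center, dtype=float).reshape(3)

    def fn(p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        return radius - np.linalg.norm(p - c, axis=-1)

    return Phantom(
        implicit_fn=fn,
        analytic_volume=4.0 / 3.0 * np.pi * radius ** 3,
        analytic_area=4.0 * np.pi * radius ** 2,
        description=f"sphere r={radius} at {tuple(c)}",
    )


def _ellipsoid_signed(p: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Approximate signed distance to an axis-aligned ellipsoid at the origin.

    ``min(radii) * (1 - |p / radii|)`` — exact for a sphere, a smooth
    monotone inside/outside indicator otherwise (positive inside).
    """
    q = np.linalg.norm(p / radii, axis=-1)
    return float(np.min(radii)) * (1.0 - q)


def make_bladder_phantom(
    outer_radii=(24.0, 20.0, 18.0),
    wall_thickness: float = 3.0,
    lesion_count: int = 1,
    lesion_radius: float = 4.0,
    seed: int = 0,
    ground_truth_resolution: int = 96,
) -> Phantom:
    """Hollow-organ phantom: ellipsoidal wall shell plus papillary wall lesions.

    The solid is the union of the shell between an outer ellipsoid and the
    inner ellipsoid (radii reduced by ``wall_thickness``) with
    ``lesion_count`` spheres of radius ``lesion_radius`` centred on the inner
    wall at seeded uniform-random directions, emulating broad-based papillary
    masses protruding into the lumen.  Ground truths are estimated on a
    ``ground_truth_resolution``^3 grid (volume by voxel counting, area by
    iso-surface triangulation) and flagged approximate.

    Identical ``seed`` and parameters give an identical phantom.
    """
    radii = np.asarray(outer_radii, dtype=float).reshape(3)
    if not wall_thickness > 0:
        raise InvalidParameterError(f"wall_thickness must be > 0, got {wall_thickness}")
    if not lesion_radius > 0:
        raise InvalidParameterError(f"lesion_radius must be > 0, got {lesion_radius}")
    if lesion_count < 0:
        raise InvalidParameterError(f"lesion_count must be >= 0, got {lesion_count}")
    if not np.all(radii > wall_thickness):
        raise InvalidParameterError(
            f"all outer radii must exceed wall_thickness, got {radii} vs {wall_thickness}")
    inner = radii - wall_thickness
    if lesion_count and lesion_radius >= np.min(inner):
        raise InvalidParameterError(
            f"lesion_radius {lesion_radius} does not fit in lumen (min inner radius {np.min(inner)})")

    rng = np.random.default_rng(seed)
    # Lesion centres sit on the inner wall, spread by rejecting directions
    # closer than ~one lesion diameter to an already placed one.
    centers = []
    for _ in range(lesion_count):
        for _attempt in range(1000):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            c = d * inner  # point on the inner ellipsoid
            if all(np.linalg.norm(c - c0) > 2.5 * lesion_radius for c0 in centers):
                centers.append(c)
                break
        else:  # pragma: no cover - only reachable with absurd lesion counts
            raise InvalidParameterError("could not place lesions without overlap")
    centers = np.asarray(centers).reshape(-1, 3)

    def fn(p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        outer_s = _ellipsoid_signed(p, radii)
        inner_s = _ellipsoid_signed(p, inner)
        shell = np.minimum(outer_s, -inner_s)
        out = shell
        for c in centers:
            lesion = lesion_radius - np.linalg.norm(p - c, axis=-1)
            # keep lesions inside the organ: clip against the outer ellipsoid
            out = np.maximum(out, np.minimum(lesion, outer_s))
        return out

    # numeric ground truths on a fine grid spanning the outer ellipsoid
    n = int(ground_truth_resolution)
    half = float(np.max(radii)) * 1.05
    axes = [np.linspace(-half, half, n)] * 3
    h = axes[0][1] - axes[0][0]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    vals = fn(grid)
    volume = float(np.count_nonzero(vals > 0)) * h ** 3
    verts, faces_, _, _ = measure.marching_cubes(vals, level=0.0, spacing=(h, h, h))
    tri = verts[faces_]
    area = float(np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1).sum() / 2.0)

    return Phantom(
        implicit_fn=fn,
        analytic_volume=volume,
        analytic_area=area,
        description=(f"bladder shell radii={tuple(float(r) for r in radii)} wall={wall_thickness} "
                     f"lesions={lesion_count} r={lesion_radius} seed={seed}"),
        approximate=True,
    )


def voxelize(phantom: Phantom, dims, spacing, origin) -> VoxelGrid:
    """Sample a phantom's implicit function on a regular grid.

    The value at index (i, j, k) is ``implicit_fn(origin + index * spacing)``;
    voxel centres sit at integer indices.
    """
    dims = tuple(int(d) for d in np.asarray(dims).reshape(3))
    if any(d < 2 for d in dims):
        raise InvalidParameterError(f"dims must be >= 2 per axis, got {dims}")
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    if not np.all(spacing > 0):
        raise InvalidParameterError(f"spacing must be positive, got {spacing}")
    origin = np.asarray(origin, dtype=float).reshape(3)
    axes = [origin[a] + spacing[a] * np.arange(dims[a]) for a in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    values = np.asarray(phantom.implicit_fn(pts), dtype=np.float64)
    return VoxelGrid(values=values, spacing=spacing, origin=origin)


def make_blob_grid(dims=(32, 32, 32), seed: int = 0, sigma: float = 2.5,
                   threshold_percentile: float = 65.0) -> VoxelGrid:
    """Smooth random blob field for surface-extraction stress tests.

    Seeded white noise is Gaussian-smoothed (``sigma`` in voxels) and shifted
    so the chosen percentile maps to zero; the positive region then forms
    smooth blob-like structures occupying roughly ``100 - threshold_percentile``
    percent of the volume — a rough stand-in for compact soft-tissue
    structures at CT slice resolution.  Unit spacing, origin at zero.
    """
    dims = tuple(int(d) for d in np.asarray(dims).reshape(3))
    rng = np.random.default_rng(seed)
    noise = rng.normal(size=dims)
    smooth = gaussian_filter(noise, sigma=sigma)
    values = smooth - np.percentile(smooth, threshold_percentile)
    return VoxelGrid(values=values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0))


def _polygon_area(poly: np.ndarray) -> float:
    """Signed shoelace area; positive for counterclockwise orientation."""
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def contours_from_grid(grid: VoxelGrid, level: float = 0.0,
                       slice_axis: int = 2) -> ContourSet:
    """Extract closed iso-level polygons from every slice of a grid.

    For each slice perpendicular to ``slice_axis`` the in-plane scalar field
    is contoured at ``level`` (sub-voxel linear interpolation via
    skimage.measure.find_contours); only closed contours are kept, oriented
    counterclockwise in (first in-plane axis, second in-plane axis) world
    coordinates.  Slices with no crossing contribute no polygons.

    Raises ``InvalidInputError`` for a slice that is constant and exactly at
    ``level`` (its contour is ambiguous).
    """
    if slice_axis not in (0, 1, 2):
        raise InvalidParameterError(f"slice_axis must be 0, 1 or 2, got {slice_axis}")
    axes_ip = tuple(a for a in (0, 1, 2) if a != slice_axis)
    if any(grid.dims[a] < 2 for a in axes_ip):
        raise InvalidInputError("need >= 2 samples per in-plane axis")

    slices = []
    for idx in range(grid.dims[slice_axis]):
        plane = np.take(grid.values, idx, axis=slice_axis)
        if np.all(plane == level):
            raise InvalidInputError(
                f"slice {idx} is constant at the contour level; contour undefined")
        polys = []
        for c in measure.find_contours(plane, level=level):
            if not np.allclose(c[0], c[-1]):
                continue  # open contour hits the grid border; not a closed line
            c = c[:-1]
            if len(c) < 3:
                continue
            # find_contours gives (row, col) = (axes_ip[0], axes_ip[1]) index coords
            world = np.empty_like(c)
            world[:, 0] = grid.origin[axes_ip[0]] + c[:, 0] * grid.spacing[axes_ip[0]]
            world[:, 1] = grid.origin[axes_ip[1]] + c[:, 1] * grid.spacing[axes_ip[1]]
            if _polygon_area(world) < 0:
                world = world[::-1]
            polys.append(world)
        if polys:
            slices.append(SliceContours(index=idx, polygons=polys))
    return ContourSet(slice_axis=slice_axis, slices=slices)
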