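"""End-to-end reconstruction pipeline with a machine-readable run report.

``run_pipeline`` chains the stages a CT reconstruction session performs —
phantom generation (or volume loading), tri-state classification, surface
extraction with normals, simplification — writing the requested artifact
files and a JSON report of parameters, seed and per-stage mesh statistics.
The report is validated by the :class:`RunReport` pydantic model, whose
``model_json_schema()`` is the shipped schema.

Given the same configuration and seed, two runs produce byte-identical
meshes: every stage is deterministic and the only randomness (phantom lesion
placement, blob noise) is driven by the explicit seed.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field

from . import __version__
from .core import TriMesh, TriStateField
from .errors import CtsurfError, InvalidParameterError
from .field import classify_implicit, classify_voxels
from .meshkit import mesh_stats, write_mesh
from .phantom import contours_from_grid, make_bladder_phantom, make_sphere, voxelize
from .simplify import SimplifyConfig, decimate
from .surface import extract_surface, vertex_normals
from .volio import load_contours, load_volume, save_contours, save_field, save_volume

log = logging.getLogger("ctsurf")

__all__ = ["PipelineConfig", "RunReport", "StageStats", "run_pipeline"]


class PipelineConfig(BaseModel):
    """Configuration of one pipeline run (flags and YAML mirror these fields)."""

    # input: either a synthetic phantom or a volume / contour file
    shape: Literal["sphere", "bladder"] = "sphere"
    radius: float = 12.0
    input_volume: Optional[str] = None
    input_contours: Optional[str] = None

    dims: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    origin: Optional[tuple[float, float, float]] = None  # default: centre the grid on 0

    use_contours: bool = False   # classify via per-slice contours instead of the implicit samples
    on_tolerance: float = 0.0
    zero_tolerance: float = 0.0
    rule: Literal["even-odd", "any"] = "even-odd"

    simplify_ratio: Optional[float] = None
    simplify_faces: Optional[int] = None
    ct: float = 1.0
    cx: float = 1.0
    cg: float = 1.0

    seed: int = 0
    out_mesh: Optional[str] = None
    out_simplified: Optional[str] = None
    out_volume: Optional[str] = None
    out_field: Optional[str] = None
    out_contours: Optional[str] = None
    report: Optional[str] = None


class StageStats(BaseModel):
    stage: str
    seconds: float
    n_vertices: int = 0
    n_edges: int = 0
    n_faces: int = 0
    euler_characteristic: int = 0
    watertight: bool = False
    surface_area: float = 0.0
    enclosed_volume: float = 0.0


class RunReport(BaseModel):
    """The shipped report schema; serialized next to the output meshes."""

    version: str
    seed: int
    parameters: dict
    stages: list[StageStats] = Field(default_factory=list)


def _mesh_stage(report: RunReport, name: str, mesh: TriMesh, t0: float) -> None:
    s = mesh_stats(mesh)
    report.stages.append(StageStats(stage=name, seconds=time.time() - t0, **s.as_dict()))


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the configured stages in order and return the run report.

    Raises the originating error (stage named in the log and the message) on
    failure; the CLI maps that to a nonzero exit status.
    """
    report = RunReport(version=__version__, seed=config.seed,
                       parameters=config.model_dump())
    dims = np.asarray(config.dims)
    spacing = np.asarray(config.spacing)
    origin = (np.asarray(config.origin) if config.origin is not None
              else -spacing * (dims - 1) / 2.0)

    # --- acquire a volume -------------------------------------------------
    t0 = time.time()
    if config.input_volume:
        p = Path(config.input_volume)
        if not p.exists():
            raise InvalidParameterError(f"input volume not found: {p}")
        grid = load_volume(p)
        log.info("loaded volume %s %s", p, grid.dims)
    else:
        if config.shape == "sphere":
            ph = make_sphere(config.radius)
        else:
            ph = make_bladder_phantom(seed=config.seed)
        grid = voxelize(ph, dims, spacing, origin)
        log.info("voxelized %s on %s grid", ph.description, tuple(grid.dims))
    if config.out_volume:
        save_volume(grid, config.out_volume)
    report.stages.append(StageStats(stage="volume", seconds=time.time() - t0))

    # --- tri-state classification ----------------------------------------
    t0 = time.time()
    if config.input_contours:
        p = Path(config.input_contours)
        if not p.exists():
            raise InvalidParameterError(f"input contours not found: {p}")
        contours = load_contours(p)
        field = classify_voxels(grid.dims, contours, grid.spacing, grid.origin,
                                on_tolerance=config.on_tolerance, rule=config.rule)
    elif config.use_contours:
        contours = contours_from_grid(grid)
        if config.out_contours:
            save_contours(contours, config.out_contours)
        field = classify_voxels(grid.dims, contours, grid.spacing, grid.origin,
                                on_tolerance=config.on_tolerance, rule=config.rule)
    else:
        field = classify_implicit(grid, zero_tolerance=config.zero_tolerance)
    if config.out_field:
        save_field(field, config.out_field)
    counts = {int(k): int(v) for k, v in
              zip(*np.unique(field.labels, return_counts=True))}
    log.info("classified voxels: %s", counts)
    report.stages.append(StageStats(stage="classify", seconds=time.time() - t0))

    # --- surface extraction ----------------------------------------------
    t0 = time.time()
    n_cells = int(np.prod(np.asarray(field.dims) + 1))
    mesh = extract_surface(field)
    mesh = vertex_normals(field, mesh)
    log.info("extracted surface: %d cells -> %d triangles in %.2fs",
             n_cells, mesh.n_faces, time.time() - t0)
    if config.out_mesh:
        write_mesh(mesh, config.out_mesh)
    _mesh_stage(report, "reconstruct", mesh, t0)

    # --- simplification ---------------------------------------------------
    if config.simplify_ratio is not None or config.simplify_faces is not None:
        t0 = time.time()
        scfg = SimplifyConfig(Ct=config.ct, Cx=config.cx, Cg=config.cg,
                              target_faces=config.simplify_faces,
                              target_ratio=config.simplify_ratio)
        simplified = decimate(mesh, scfg)
        log.info("simplified %d -> %d faces in %.2fs",
                 mesh.n_faces, simplified.n_faces, time.time() - t0)
        if config.out_simplified:
            write_mesh(simplified, config.out_simplified)
        _mesh_stage(report, "simplify", simplified, t0)

    if config.report:
        Path(config.report).write_text(report.model_dump_json(indent=2))
    return report
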