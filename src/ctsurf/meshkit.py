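"""Mesh statistics and interchange formats.

``mesh_stats`` computes the bookkeeping every stage of the pipeline is
checked against: vertex/edge/face counts, Euler characteristic, area,
watertightness and the signed enclosed volume (divergence-theorem sum of
signed tetrahedra against the origin — reference-point independent exactly
when the mesh is watertight).

I/O covers the three formats surgical-planning tools exchange:

* binary little-endian STL (80-byte header, uint32 triangle count),
* ascii PLY with x/y/z vertex properties and ``vertex_indices`` face lists,
* Wavefront OBJ with 1-based indices.

Faces are written counterclockwise viewed from outside (outward normals).
STL stores vertices per-triangle in 32-bit floats; reading welds exactly
equal coordinates back into an indexed mesh, so a write/read round trip
preserves connectivity up to vertex re-indexing and coordinates to float32
precision.  PLY and OBJ round-trip coordinates exactly (repr precision).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import TriMesh
from .errors import MeshFormatError, MeshParseError

__all__ = ["MeshStats", "mesh_stats", "read_mesh", "write_mesh"]


@dataclass
class MeshStats:
    n_vertices: int
    n_edges: int
    n_faces: int
    euler_characteristic: int
    watertight: bool
    surface_area: float
    enclosed_volume: float

    def as_dict(self) -> dict:
        return {
            "n_vertices": self.n_vertices,
            "n_edges": self.n_edges,
            "n_faces": self.n_faces,
            "euler_characteristic": self.euler_characteristic,
            "watertight": self.watertight,
            "surface_area": self.surface_area,
            "enclosed_volume": self.enclosed_volume,
        }


def mesh_stats(mesh: TriMesh) -> MeshStats:
    """Counts, Euler characteristic, watertightness, area and signed volume.

    Volume is ``(1/6) * sum(v0 . (v1 x v2))`` over faces — positive for
    outward-oriented closed meshes, meaningful only when watertight.  An
    empty mesh reports zeros and is not watertight.
    """
    if mesh.n_faces == 0:
        return MeshStats(mesh.n_vertices, 0, 0, mesh.n_vertices, False, 0.0, 0.0)
    e = np.vstack([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]])
    e.sort(axis=1)
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    n_e = len(uniq)
    watertight = bool((counts == 2).all())
    v, f = mesh.vertices, mesh.faces
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    area = float(np.linalg.norm(cross, axis=1).sum() / 2.0)
    volume = float(np.einsum("ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]])).sum() / 6.0)
    return MeshStats(
        n_vertices=mesh.n_vertices,
        n_edges=n_e,
        n_faces=mesh.n_faces,
        euler_characteristic=mesh.n_vertices - n_e + mesh.n_faces,
        watertight=watertight,
        surface_area=area,
        enclosed_volume=volume,
    )


# ---------------------------------------------------------------------------
# STL (binary little-endian)


def _write_stl(mesh: TriMesh, path: Path) -> None:
    v, f = mesh.vertices.astype(np.float32), mesh.faces
    with open(path, "wb") as fh:
        fh.write(b"ctsurf binary STL".ljust(80, b" "))
        fh.write(struct.pack("<I", len(f)))
        if len(f):
            tri = v[f]  # (m, 3, 3)
            n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]).astype(np.float64)
            mag = np.linalg.norm(n, axis=1)
            n = (n / np.where(mag == 0, 1.0, mag)[:, None]).astype(np.float32)
            rec = np.zeros(len(f), dtype=[("n", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")])
            rec["n"] = n
            rec["v"] = tri
            fh.write(rec.tobytes())


def _read_stl(path: Path) -> TriMesh:
    raw = path.read_bytes()
    if len(raw) < 84:
        raise MeshParseError("STL file shorter than 84-byte header", offset=len(raw))
    if raw[:5] == b"solid" and b"facet" in raw[:500]:
        raise MeshParseError("ascii STL is not supported; write binary STL", offset=0)
    (count,) = struct.unpack_from("<I", raw, 80)
    expected = 84 + 50 * count
    if len(raw) != expected:
        raise MeshParseError(
            f"STL length mismatch: header says {count} triangles ({expected} bytes), "
            f"file has {len(raw)} bytes", offset=84)
    if count == 0:
        return TriMesh(np.empty((0, 3)), np.empty((0, 3), dtype=np.int64))
    rec = np.frombuffer(raw, dtype=[("n", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")],
                        count=count, offset=84)
    tri = rec["v"].reshape(-1, 3).astype(np.float64)
    # weld exactly-equal float32 coordinates back into an indexed mesh
    uniq, inverse = np.unique(tri, axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3).astype(np.int64)
    return TriMesh(uniq, faces)


# ---------------------------------------------------------------------------
# ascii PLY


def _write_ply(mesh: TriMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\ncomment ctsurf\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for p in mesh.vertices:
            fh.write(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def _read_ply(path: Path) -> TriMesh:
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise MeshParseError("not a PLY file (missing 'ply' magic)", line=1)
    n_v = n_f = None
    i = 1
    fmt_seen = False
    elements: list[tuple[str, int]] = []
    while i < len(lines):
        tok = lines[i].split()
        if not tok or tok[0] == "comment":
            i += 1
            continue
        if tok[0] == "format":
            if tok[1] != "ascii":
                raise MeshParseError(f"unsupported PLY format '{tok[1]}'", line=i + 1)
            fmt_seen = True
        elif tok[0] == "element":
            elements.append((tok[1], int(tok[2])))
        elif tok[0] == "end_header":
            i += 1
            break
        elif tok[0] != "property":
            raise MeshParseError(f"unexpected header line {lines[i]!r}", line=i + 1)
        i += 1
    else:
        raise MeshParseError("PLY header without end_header", line=len(lines))
    if not fmt_seen:
        raise MeshParseError("PLY header missing format line", line=1)
    counts = dict(elements)
    n_v, n_f = counts.get("vertex", 0), counts.get("face", 0)

    verts = np.empty((n_v, 3))
    for r in range(n_v):
        if i + r >= len(lines):
            raise MeshParseError("unexpected end of file in vertex block", line=len(lines))
        tok = lines[i + r].split()
        if len(tok) < 3:
            raise MeshParseError(f"vertex line needs 3 coordinates, got {lines[i + r]!r}",
                                 line=i + r + 1)
        verts[r] = [float(tok[0]), float(tok[1]), float(tok[2])]
    i += n_v
    faces = np.empty((n_f, 3), dtype=np.int64)
    for r in range(n_f):
        if i + r >= len(lines):
            raise MeshParseError("unexpected end of file in face block", line=len(lines))
        tok = lines[i + r].split()
        if not tok or int(tok[0]) != 3:
            raise MeshParseError(
                f"only triangular faces are supported, got list size {tok[0] if tok else '?'}",
                line=i + r + 1)
        if len(tok) < 4:
            raise MeshParseError(f"truncated face line {lines[i + r]!r}", line=i + r + 1)
        faces[r] = [int(tok[1]), int(tok[2]), int(tok[3])]
    return TriMesh(verts, faces)


# ---------------------------------------------------------------------------
# Wavefront OBJ


def _write_obj(mesh: TriMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# ctsurf OBJ\n")
        for p in mesh.vertices:
            fh.write(f"v {float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def _read_obj(path: Path) -> TriMesh:
    verts: list = []
    faces: list = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        tok = line.split()
        if not tok or tok[0] in ("#", "vn", "vt", "o", "g", "s", "usemtl", "mtllib"):
            continue
        if tok[0] == "v":
            if len(tok) < 4:
                raise MeshParseError(f"vertex line needs 3 coordinates: {line!r}", line=ln)
            verts.append([float(tok[1]), float(tok[2]), float(tok[3])])
        elif tok[0] == "f":
            if len(tok) != 4:
                raise MeshParseError(f"only triangular faces are supported: {line!r}", line=ln)
            idx = [int(t.split("/")[0]) for t in tok[1:]]
            faces.append([i - 1 if i > 0 else len(verts) + i for i in idx])
        else:
            raise MeshParseError(f"unrecognized OBJ token {tok[0]!r}", line=ln)
    return TriMesh(np.asarray(verts, dtype=np.float64).reshape(-1, 3),
                   np.asarray(faces, dtype=np.int64).reshape(-1, 3))


_WRITERS = {".stl": _write_stl, ".ply": _write_ply, ".obj": _write_obj}
_READERS = {".stl": _read_stl, ".ply": _read_ply, ".obj": _read_obj}


def write_mesh(mesh: TriMesh, path, fmt: str | None = None) -> None:
    """Write a mesh as STL, PLY or OBJ, chosen by ``fmt`` or file extension."""
    path = Path(path)
    ext = f".{fmt.lower()}" if fmt else path.suffix.lower()
    writer = _WRITERS.get(ext)
    if writer is None:
        raise MeshFormatError(f"unknown mesh format {ext!r} (use stl, ply or obj)")
    writer(mesh, path)


def read_mesh(path, fmt: str | None = None) -> TriMesh:
    """Read an STL, PLY or OBJ file into a :class:`TriMesh`."""
    path = Path(path)
    ext = f".{fmt.lower()}" if fmt else path.suffix.lower()
    reader = _READERS.get(ext)
    if reader is None:
        raise MeshFormatError(f"unknown mesh format {ext!r} (use stl, ply or obj)")
    return reader(path)
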