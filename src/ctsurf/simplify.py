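"""Mesh simplification by priority-ranked edge collapse (the deletion algorithm).

Reconstructed CT surfaces carry far more triangles than display or planning
needs; the deletion algorithm removes edges greedily, cheapest first, under
the priority function

    Y(s) = Ct * T(s) + Cx * X(s) + Cg * G(s)

where, for a candidate edge ``s``:

* ``T(s)`` — *flatness* of the neighbourhood: ``max(1 - L̇_i · L̇_j)`` over all
  pairs of unit normals of triangles incident to either endpoint of ``s``.
  0 for a locally planar neighbourhood, 2 for a fold-back.
* ``X(s)`` — *shape coefficient*: ``1 - min q`` over incident triangles, with
  the mean-ratio triangle quality ``q = 4*sqrt(3)*area / (a^2 + b^2 + c^2)``
  (1 for equilateral, 0 when degenerate).
* ``G(s)`` — edge length divided by ``length_scale`` (default: the input
  mesh's mean edge length), making the three terms commensurable.

The edge of globally minimal Y (ties broken by the smaller sorted
vertex-index pair) is collapsed to its midpoint, provided the collapse passes
the link condition (manifoldness preserved) and flips no surviving face
normal by more than 90 degrees.  Priorities of edges in the modified
neighbourhood are recomputed and the loop continues until the face target is
reached or no valid edge remains.  A priority queue with lazy invalidation
makes this near-linear; its behaviour is identical to full recomputation.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .core import TriMesh
from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "SimplifyConfig",
    "EdgeRecord",
    "edge_flatness",
    "shape_coefficient",
    "edge_priority",
    "is_collapse_valid",
    "decimate",
]

_SQRT3_4 = 4.0 * np.sqrt(3.0)


@dataclass
class SimplifyConfig:
    """Weights and stopping target for the deletion algorithm.

    Exactly one of ``target_faces`` / ``target_ratio`` must be set; weights
    are nonnegative with at least one positive.  ``length_scale`` (mm)
    normalizes G; None means the input mesh's mean edge length.
    """

    Ct: float = 1.0
    Cx: float = 1.0
    Cg: float = 1.0
    target_faces: int | None = None
    target_ratio: float | None = None
    length_scale: float | None = None

    def __post_init__(self):
        if min(self.Ct, self.Cx, self.Cg) < 0:
            raise InvalidParameterError("weights must be nonnegative")
        if max(self.Ct, self.Cx, self.Cg) <= 0:
            raise InvalidParameterError("at least one weight must be positive")
        if (self.target_faces is None) == (self.target_ratio is None):
            raise InvalidParameterError(
                "exactly one of target_faces / target_ratio must be set")
        if self.target_faces is not None and self.target_faces < 4:
            raise InvalidParameterError(f"target_faces must be >= 4, got {self.target_faces}")
        if self.target_ratio is not None and not 0 < self.target_ratio <= 1:
            raise InvalidParameterError(f"target_ratio must be in (0, 1], got {self.target_ratio}")
        if self.length_scale is not None and not self.length_scale > 0:
            raise InvalidParameterError("length_scale must be positive")

    def resolve_target(self, n_faces: int) -> int:
        if self.target_faces is not None:
            t = self.target_faces
        else:
            t = int(round(self.target_ratio * n_faces))
        if t < 4:
            raise InvalidParameterError(f"resolved face target {t} is below 4")
        return t


@dataclass
class EdgeRecord:
    """Priority bookkeeping for one candidate edge s = (u, v), u < v."""

    edge: tuple[int, int]
    T: float
    X: float
    G: float
    Y: float


# ---------------------------------------------------------------------------
# geometry kernels shared by the public API and the decimation loop


def _face_normals_unit(vertices: np.ndarray, tri_idx: np.ndarray) -> np.ndarray:
    """Unit normals of faces given as an (m, 3) vertex-index array."""
    p = vertices[tri_idx]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    mag = np.linalg.norm(n, axis=1)
    mag = np.where(mag < 1e-300, 1.0, mag)
    return n / mag[:, None]


def _flatness_kernel(vertices: np.ndarray, tri_idx: np.ndarray) -> float:
    """max(1 - n_i . n_j) over all unordered pairs of incident-face normals."""
    n = _face_normals_unit(vertices, tri_idx)
    if len(n) == 1:
        return 0.0
    dots = n @ n.T
    return float(1.0 - dots.min())


def _quality_kernel(vertices: np.ndarray, tri_idx: np.ndarray) -> np.ndarray:
    """Mean-ratio triangle quality q = 4*sqrt(3)*A / (a^2 + b^2 + c^2).

    1 for equilateral, 0 in the degenerate (zero-area) limit; 0 for a
    zero-perimeter triangle.
    """
    p = vertices[tri_idx]
    a2 = ((p[:, 1] - p[:, 0]) ** 2).sum(axis=1)
    b2 = ((p[:, 2] - p[:, 1]) ** 2).sum(axis=1)
    c2 = ((p[:, 0] - p[:, 2]) ** 2).sum(axis=1)
    denom = a2 + b2 + c2
    area = 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(denom > 0, _SQRT3_4 * area / denom, 0.0)
    return q


def _incident_faces(mesh: TriMesh, u: int, v: int) -> np.ndarray:
    f = mesh.faces
    mask = (f == u).any(axis=1) | (f == v).any(axis=1)
    return f[mask]


def _edge_faces(mesh: TriMesh, u: int, v: int) -> np.ndarray:
    f = mesh.faces
    mask = (f == u).any(axis=1) & (f == v).any(axis=1)
    return f[mask]


def edge_flatness(mesh: TriMesh, edge) -> float:
    """T(s): flatness of the triangles around edge s.

    Max of ``1 - L̇_i · L̇_j`` over all pairs of unit normals of the triangles
    incident to either endpoint; 0 when coplanar, 2 at a fold-back.
    """
    u, v = int(edge[0]), int(edge[1])
    inc = _incident_faces(mesh, u, v)
    if not len(inc):
        raise InvalidInputError(f"edge ({u}, {v}) has no incident triangles")
    if not len(_edge_faces(mesh, u, v)):
        raise InvalidInputError(f"({u}, {v}) is not an edge of the mesh")
    return _flatness_kernel(mesh.vertices, inc)


def shape_coefficient(mesh: TriMesh, edge) -> float:
    """X(s): 1 − (worst incident-triangle quality), in [0, 1].

    Quality is the mean ratio ``4*sqrt(3)*area/(a^2+b^2+c^2)``; a
    neighbourhood of equilateral triangles scores 0, one containing a
    degenerate triangle scores 1.
    """
    u, v = int(edge[0]), int(edge[1])
    inc = _incident_faces(mesh, u, v)
    if not len(inc):
        raise InvalidInputError(f"edge ({u}, {v}) has no incident triangles")
    return float(1.0 - _quality_kernel(mesh.vertices, inc).min())


def edge_priority(mesh: TriMesh, edge, config: SimplifyConfig,
                  length_scale: float | None = None) -> EdgeRecord:
    """Full priority record Y(s) = Ct*T + Cx*X + Cg*G for one edge.

    ``length_scale`` overrides the config's; when both are None the mesh's
    mean edge length is used.
    """
    u, v = sorted((int(edge[0]), int(edge[1])))
    scale = length_scale or config.length_scale
    if scale is None:
        e = mesh.edges_unique()
        scale = float(np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1).mean())
    T = edge_flatness(mesh, (u, v))
    X = shape_coefficient(mesh, (u, v))
    G = float(np.linalg.norm(mesh.vertices[u] - mesh.vertices[v])) / scale
    Y = config.Ct * T + config.Cx * X + config.Cg * G
    return EdgeRecord(edge=(u, v), T=T, X=X, G=G, Y=Y)


# ---------------------------------------------------------------------------
# collapse validity


def _valid_kernel(vertices: np.ndarray, v_faces: dict[int, set[int]],
                  face_v: list, u: int, v: int) -> bool:
    """Link condition + normal-flip test for collapsing (u, v) to its midpoint."""
    shared = v_faces[u] & v_faces[v]
    if len(shared) not in (1, 2):
        return False
    # link condition: common vertex neighbours of u and v must be exactly the
    # vertices opposite the shared faces
    def neighbours(w):
        s = set()
        for fi in v_faces[w]:
            s.update(face_v[fi])
        s.discard(w)
        return s

    opp = set()
    for fi in shared:
        opp.update(face_v[fi])
    opp -= {u, v}
    if neighbours(u) & neighbours(v) != opp:
        return False

    # normal flip: no surviving face may rotate by more than 90 degrees
    mid = 0.5 * (vertices[u] + vertices[v])
    for fi in (v_faces[u] | v_faces[v]) - shared:
        tri = face_v[fi]
        p_old = np.array([vertices[w] for w in tri])
        p_new = np.array([mid if w in (u, v) else vertices[w] for w in tri])
        n_old = np.cross(p_old[1] - p_old[0], p_old[2] - p_old[0])
        n_new = np.cross(p_new[1] - p_new[0], p_new[2] - p_new[0])
        if np.linalg.norm(n_new) < 1e-300:
            return False
        if np.dot(n_old, n_new) < 0:
            return False
    return True


def is_collapse_valid(mesh: TriMesh, edge) -> bool:
    """Whether collapsing ``edge`` to its midpoint preserves a manifold mesh.

    Public wrapper over the same test the decimation loop applies: the link
    condition and the 90-degree normal-flip guard.
    """
    u, v = int(edge[0]), int(edge[1])
    v_faces: dict[int, set[int]] = {w: set() for w in range(mesh.n_vertices)}
    face_v = [tuple(f) for f in mesh.faces]
    for fi, tri in enumerate(face_v):
        for w in tri:
            v_faces[w].add(fi)
    return _valid_kernel(mesh.vertices, v_faces, face_v, u, v)


# ---------------------------------------------------------------------------
# the decimation loop


def _check_edge_manifold(mesh: TriMesh) -> None:
    e = np.vstack([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]])
    e.sort(axis=1)
    _, counts = np.unique(e, axis=0, return_counts=True)
    if (counts > 2).any():
        raise InvalidInputError("mesh is not edge-manifold (an edge borders > 2 faces)")


def decimate(mesh: TriMesh, config: SimplifyConfig,
             trace: list | None = None) -> TriMesh:
    """Run the deletion algorithm until the face target is met.

    Repeatedly collapses the valid edge of minimal Y (ties by the smaller
    sorted vertex pair) onto its midpoint.  Interior collapses remove exactly
    one vertex, three edges and two faces, so watertightness and Euler
    characteristic are preserved.  Stops when ``n_faces <= target`` or no
    valid edge remains.

    If ``trace`` is a list, a tuple ``(u, v, Y)`` is appended for every
    collapse actually performed (working vertex indices, i.e. indices into
    the *input* mesh's vertex array), enabling step-by-step verification
    against an exhaustive recomputation.
    """
    if mesh.n_faces == 0:
        raise InvalidInputError("cannot decimate an empty mesh")
    _check_edge_manifold(mesh)
    target = config.resolve_target(mesh.n_faces)
    if mesh.n_faces <= target:
        return mesh.copy()

    vertices = mesh.vertices.copy()
    face_v: list = [tuple(int(w) for w in f) for f in mesh.faces]
    alive_f = [True] * len(face_v)
    v_faces: dict[int, set[int]] = {w: set() for w in range(len(vertices))}
    for fi, tri in enumerate(face_v):
        for w in tri:
            v_faces[w].add(fi)
    n_faces = len(face_v)

    scale = config.length_scale
    if scale is None:
        e = mesh.edges_unique()
        scale = float(np.linalg.norm(vertices[e[:, 0]] - vertices[e[:, 1]], axis=1).mean())

    def current_edges_of(vset) -> set[tuple[int, int]]:
        out = set()
        for w in vset:
            for fi in v_faces[w]:
                a, b, c = face_v[fi]
                for p, q in ((a, b), (b, c), (c, a)):
                    out.add((p, q) if p < q else (q, p))
        return out

    def priority_of(u: int, v: int) -> float:
        inc_ids = v_faces[u] | v_faces[v]
        inc = np.array([face_v[fi] for fi in inc_ids])
        T = _flatness_kernel(vertices, inc)
        X = float(1.0 - _quality_kernel(vertices, inc).min())
        G = float(np.linalg.norm(vertices[u] - vertices[v])) / scale
        return config.Ct * T + config.Cx * X + config.Cg * G

    stamp: dict[tuple[int, int], int] = {}
    heap: list = []

    def push(u: int, v: int):
        key = (u, v)
        stamp[key] = stamp.get(key, 0) + 1
        heapq.heappush(heap, (priority_of(u, v), u, v, stamp[key]))

    for (u, v) in current_edges_of(v_faces.keys()):
        push(u, v)

    while n_faces > target and heap:
        Y, u, v, st = heapq.heappop(heap)
        key = (u, v)
        if stamp.get(key) != st:
            continue  # stale entry; a fresher one is in the heap
        if not (v_faces.get(u) and v_faces.get(v)):
            continue
        shared = v_faces[u] & v_faces[v]
        if not shared:
            continue  # no longer an edge
        if not _valid_kernel(vertices, v_faces, face_v, u, v):
            # invalid until its neighbourhood changes; recomputation re-pushes it
            continue

        if trace is not None:
            trace.append((u, v, Y))

        # collapse v into u at the edge midpoint
        vertices[u] = 0.5 * (vertices[u] + vertices[v])
        for fi in shared:
            alive_f[fi] = False
            for w in face_v[fi]:
                v_faces[w].discard(fi)
            n_faces -= 1
        for fi in list(v_faces[v]):
            tri = tuple(u if w == v else w for w in face_v[fi])
            face_v[fi] = tri
            v_faces[v].discard(fi)
            v_faces[u].add(fi)
        del v_faces[v]

        # recompute priorities in the modified neighbourhood
        region = {u}
        for fi in v_faces[u]:
            region.update(face_v[fi])
        for (p, q) in current_edges_of(region):
            push(p, q)

    # compact the result
    faces = np.array([face_v[fi] for fi in range(len(face_v)) if alive_f[fi]],
                     dtype=np.int64).reshape(-1, 3)
    used = np.unique(faces) if faces.size else np.array([], dtype=np.int64)
    remap = np.full(len(vertices), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriMesh(vertices[used], remap[faces] if faces.size else faces)
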