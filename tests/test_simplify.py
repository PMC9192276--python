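import numpy as np
import pytest

from ctsurf import (SimplifyConfig, decimate, edge_flatness, edge_priority,
                    extract_surface, classify_implicit, is_collapse_valid, make_blob_grid,
                    mesh_stats, shape_coefficient)
from ctsurf.core import TriMesh
from ctsurf.errors import InvalidInputError, InvalidParameterError

from conftest import sphere_field


def two_triangle_strip(dihedral_deg: float) -> TriMesh:
    """Two unit-edge triangles sharing edge (0, 1), folded by the given angle."""
    a = np.radians(dihedral_deg)
    v = np.array([
        [0.0, 0.0, 0.0],
        [1.0, 0.0, 0.0],
        [0.5, 1.0, 0.0],
        [0.5, -np.cos(a), np.sin(a)],
    ])
    return TriMesh(v, np.array([[0, 1, 2], [1, 0, 3]]))


class TestEdgeFlatness:
    @pytest.mark.parametrize("angle,expected", [
        (0.0, 0.0),     # coplanar: identical normals
        (90.0, 1.0),    # perpendicular normals
        (180.0, 2.0),   # fold-back: opposite normals
    ])
    def test_dihedral_angles(self, angle, expected):
        mesh = two_triangle_strip(angle)
        assert edge_flatness(mesh, (0, 1)) == pytest.approx(expected, abs=1e-12)

    def test_nonexistent_edge_rejected(self, octa):
        with pytest.raises(InvalidInputError):
            edge_flatness(octa, (0, 1))  # opposite apexes share no face


class TestShapeCoefficient:
    def test_equilateral_neighbourhood_scores_zero(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
        mesh = TriMesh(v, np.array([[0, 1, 2]]))
        assert shape_coefficient(mesh, (0, 1)) == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_triangle_scores_one(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]])  # collinear
        mesh = TriMesh(v, np.array([[0, 1, 2]]))
        assert shape_coefficient(mesh, (0, 1)) == pytest.approx(1.0, abs=1e-12)

    def test_right_isoceles_value(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        mesh = TriMesh(v, np.array([[0, 1, 2]]))
        # legs 1, 1, hypotenuse sqrt(2): q = 4*sqrt(3)*(1/2) / (1+1+2) = sqrt(3)/2
        q = np.sqrt(3) / 2
        assert shape_coefficient(mesh, (0, 1)) == pytest.approx(1 - q, abs=1e-12)
        assert shape_coefficient(mesh, (0, 1)) == pytest.approx(0.1340, abs=5e-4)


class TestEdgePriority:
    def test_linear_combination(self, octa):
        cfg = SimplifyConfig(Ct=2.0, Cx=3.0, Cg=0.5, target_ratio=1.0, length_scale=1.0)
        rec = edge_priority(octa, (0, 2), cfg)
        assert rec.Y == pytest.approx(2 * rec.T + 3 * rec.X + 0.5 * rec.G, abs=1e-12)
        assert 0 <= rec.T <= 2 and 0 <= rec.X <= 1 and rec.G >= 0

    def test_length_only_priority_is_normalized_length(self, octa):
        cfg = SimplifyConfig(Ct=0.0, Cx=0.0, Cg=1.0, target_ratio=1.0, length_scale=2.0)
        rec = edge_priority(octa, (0, 2), cfg)
        length = np.linalg.norm(octa.vertices[0] - octa.vertices[2])
        assert rec.Y == pytest.approx(length / 2.0, abs=1e-12)

    def test_flat_neighbourhood_zero_priority(self):
        mesh = two_triangle_strip(0.0)
        cfg = SimplifyConfig(Ct=2.0, Cx=0.0, Cg=0.0, target_ratio=1.0)
        assert edge_priority(mesh, (0, 1), cfg).Y == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self, octa):
        cfg = SimplifyConfig(target_ratio=1.0, length_scale=1.0)
        before = edge_priority(octa, (0, 2), cfg).Y
        # rotate by an arbitrary rotation + translate
        from scipy.spatial.transform import Rotation
        R = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        moved = TriMesh(octa.vertices @ R.T + np.array([5.0, -3.0, 2.0]), octa.faces)
        after = edge_priority(moved, (0, 2), cfg).Y
        assert after == pytest.approx(before, abs=1e-9)


class TestSimplifyConfig:
    def test_rejects_all_zero_weights(self):
        with pytest.raises(InvalidParameterError):
            SimplifyConfig(Ct=0, Cx=0, Cg=0, target_ratio=0.5)

    def test_rejects_both_targets(self):
        with pytest.raises(InvalidParameterError):
            SimplifyConfig(target_ratio=0.5, target_faces=100)

    def test_rejects_small_face_target(self):
        with pytest.raises(InvalidParameterError):
            SimplifyConfig(target_faces=2)


class TestDecimate:
    def test_target_already_met_returns_unchanged(self, octa):
        out = decimate(octa, SimplifyConfig(target_faces=8))
        assert np.array_equal(out.faces, octa.faces)
        assert np.array_equal(out.vertices, octa.vertices)

    def test_below_minimal_target_rejected(self, octa):
        with pytest.raises(InvalidParameterError):
            decimate(octa, SimplifyConfig(target_faces=2))

    def test_non_manifold_input_rejected(self):
        # three faces sharing one edge
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1]], dtype=float)
        mesh = TriMesh(v, np.array([[0, 1, 2], [1, 0, 3], [0, 1, 4]]))
        with pytest.raises(InvalidInputError):
            decimate(mesh, SimplifyConfig(target_faces=4))

    def test_each_collapse_removes_two_faces(self, sphere_mesh_5k):
        trace = []
        out = decimate(sphere_mesh_5k, SimplifyConfig(target_ratio=0.9), trace=trace)
        assert sphere_mesh_5k.n_faces - out.n_faces == 2 * len(trace)

    def test_sphere_decimation_preserves_shape_and_topology(self, sphere_mesh_5k):
        before = mesh_stats(sphere_mesh_5k)
        out = decimate(sphere_mesh_5k, SimplifyConfig(target_ratio=0.1))
        after = mesh_stats(out)
        assert after.n_faces <= 0.1 * before.n_faces + 1
        assert after.watertight and after.euler_characteristic == 2
        assert abs(after.enclosed_volume - before.enclosed_volume) <= 0.05 * before.enclosed_volume


def greedy_oracle_check(mesh: TriMesh, cfg: SimplifyConfig, scale: float):
    """Replay a decimation trace, verifying each collapse picked the globally
    minimal-Y valid edge (exhaustive recomputation every step)."""
    trace = []
    decimate(mesh, cfg, trace=trace)
    assert trace, "decimation performed no collapses"

    vertices = mesh.vertices.copy()
    faces = [tuple(f) for f in mesh.faces]
    for (u, v, y_taken) in trace:
        state = TriMesh(vertices.copy(), np.array(faces))
        edges = {tuple(sorted((f[i], f[(i + 1) % 3]))) for f in faces for i in range(3)}
        best = None
        for (p, q) in sorted(edges):
            if not is_collapse_valid(state, (p, q)):
                continue
            y = edge_priority(state, (p, q), cfg, length_scale=scale).Y
            if best is None or (y, p, q) < best:
                best = (y, p, q)
        assert best is not None
        assert (best[1], best[2]) == (u, v), f"greedy picked ({u},{v}), oracle ({best[1]},{best[2]})"
        assert y_taken == pytest.approx(best[0], abs=1e-12)
        # apply the collapse
        vertices[u] = 0.5 * (vertices[u] + vertices[v])
        faces = [tuple(u if w == v else w for w in f) for f in faces
                 if not (u in f and v in f)]


def test_greedy_selection_matches_brute_force_small_sphere():
    mesh = extract_surface(sphere_field(9, radius=7.0))
    assert mesh.n_faces <= 200
    cfg = SimplifyConfig(target_ratio=0.3, length_scale=None)
    scale = float(np.linalg.norm(
        mesh.vertices[mesh.edges_unique()[:, 0]] - mesh.vertices[mesh.edges_unique()[:, 1]],
        axis=1).mean())
    cfg = SimplifyConfig(target_ratio=0.3, length_scale=scale)
    greedy_oracle_check(mesh, cfg, scale)


def test_greedy_selection_matches_brute_force_blob():
    field = classify_implicit(make_blob_grid(dims=(7, 7, 7), seed=5, sigma=2.0,
                                             threshold_percentile=90))
    mesh = extract_surface(field)
    assert 4 < mesh.n_faces <= 200
    scale = float(np.linalg.norm(
        mesh.vertices[mesh.edges_unique()[:, 0]] - mesh.vertices[mesh.edges_unique()[:, 1]],
        axis=1).mean())
    cfg = SimplifyConfig(Ct=1.0, Cx=0.5, Cg=2.0, target_ratio=0.4, length_scale=scale)
    greedy_oracle_check(mesh, cfg, scale)


def test_euler_characteristic_preserved_on_blob(sphere_mesh_5k):
    field = classify_implicit(make_blob_grid(dims=(16, 16, 16), seed=2, sigma=2.0,
                                             threshold_percentile=70))
    mesh = extract_surface(field)
    before = mesh_stats(mesh)
    out = decimate(mesh, SimplifyConfig(target_ratio=0.3))
    after = mesh_stats(out)
    assert after.euler_characteristic == before.euler_characteristic
    assert after.watertight == before.watertight
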