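import numpy as np
import pytest
from skimage import measure

from ctsurf import classify_implicit, extract_surface, make_blob_grid, mesh_stats, vertex_normals
from ctsurf.core import TriStateField
from ctsurf.errors import InvalidInputError
from ctsurf.surface import _CASE_TABLE

from conftest import SPHERE_RADIUS, sphere_field


def chi(verts, faces):
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e.sort(axis=1)
    return len(verts) - len(np.unique(e, axis=0)) + len(faces)


class TestCaseTable:
    def test_empty_and_full_configurations_emit_nothing(self):
        assert _CASE_TABLE[0] == [] and _CASE_TABLE[255] == []

    def test_single_corner_cases_emit_one_triangle(self):
        for bit in range(8):
            assert len(_CASE_TABLE[1 << bit]) == 1

    def test_crossing_edges_all_used(self):
        # every cube edge with opposite-sign endpoints must appear in the
        # triangulation; edges with same-sign endpoints must not
        from ctsurf.surface import _EDGES
        for config in range(256):
            inside = [(config >> i) & 1 for i in range(8)]
            crossing = {i for i, (a, b) in enumerate(_EDGES) if inside[a] != inside[b]}
            used = {e for tri in _CASE_TABLE[config] for e in tri}
            assert used == crossing, f"config {config}"


class TestExtractSurface:
    def test_single_positive_voxel_yields_octahedron(self):
        labels = -np.ones((3, 3, 3), dtype=np.int8)
        labels[1, 1, 1] = 1
        mesh = extract_surface(TriStateField(labels))
        st = mesh_stats(mesh)
        assert (st.n_vertices, st.n_edges, st.n_faces) == (6, 12, 8)
        assert st.euler_characteristic == 2 and st.watertight
        # all six vertices at midpoints of the edges around the centre voxel
        offsets = np.abs(mesh.vertices - 1.0)
        assert np.allclose(np.sort(offsets, axis=1), [0.0, 0.0, 0.5])

    def test_uniform_field_yields_empty_mesh(self):
        labels = -np.ones((4, 4, 4), dtype=np.int8)
        mesh = extract_surface(TriStateField(labels))
        assert mesh.n_vertices == 0 and mesh.n_faces == 0

    def test_degenerate_dims_rejected(self):
        with pytest.raises(InvalidInputError):
            extract_surface(TriStateField(np.ones((1, 4, 4), dtype=np.int8)))

    def test_sphere_reconstruction_watertight_genus_zero(self, sphere_mesh_64):
        st = mesh_stats(sphere_mesh_64)
        assert st.watertight and st.euler_characteristic == 2
        exact = 4 / 3 * np.pi * SPHERE_RADIUS ** 3
        assert st.enclosed_volume == pytest.approx(exact, rel=0.05)

    def test_vertices_on_half_grid(self, sphere_field_64, sphere_mesh_64):
        """Every vertex is a grid point or an exact edge midpoint."""
        t = (sphere_mesh_64.vertices - sphere_field_64.origin) / (sphere_field_64.spacing / 2)
        assert np.allclose(t, np.round(t), atol=1e-9)
        # and each vertex is half-integral along at most one axis
        frac = np.round(t).astype(int) % 2
        assert (frac.sum(axis=1) <= 1).all()

    def test_inside_region_touching_border_is_closed_by_padding(self):
        labels = np.ones((4, 4, 4), dtype=np.int8)  # fills the whole grid
        st = mesh_stats(extract_surface(TriStateField(labels)))
        assert st.watertight and st.euler_characteristic == 2

    def test_zero_state_vertices_snap_to_grid_points(self):
        # +1 slab, then a plane of 0s, then -1: the surface must pass through
        # the 0-state grid points themselves
        labels = -np.ones((5, 5, 7), dtype=np.int8)
        labels[:, :, :3] = 1
        labels[:, :, 3] = 0
        mesh = extract_surface(TriStateField(labels))
        top = mesh.vertices[np.isclose(mesh.vertices[:, 2], 3.0)]
        assert len(top) > 0
        assert np.allclose(top, np.round(top))  # integer grid coordinates
        st = mesh_stats(mesh)
        assert st.watertight and st.euler_characteristic == 2

    def test_matches_reference_marching_cubes_on_blobs(self):
        """Same topology and enclosed volume as skimage's marching cubes.

        Volume is compared at level 0 (identical midpoint geometry).  The
        Euler characteristic is compared at level -0.1: on +/-1 data the
        trilinear saddle of every ambiguous face is exactly 0, so the level-0
        reference topology is an implementation tie-break, while any level
        just below 0 realizes the same 'separate the negative corners'
        convention this package fixes.
        """
        for seed in range(3):  # the full 10-field sweep runs in the acceptance suite
            field = classify_implicit(make_blob_grid(seed=seed))
            mesh = extract_surface(field)
            labp = np.pad(field.labels.astype(float), 1, constant_values=-1.0)
            v0, f0, _, _ = measure.marching_cubes(labp, level=0.0)
            ref_vol = abs(np.einsum("ij,ij->i", v0[f0[:, 0]],
                                    np.cross(v0[f0[:, 1]], v0[f0[:, 2]])).sum() / 6)
            st = mesh_stats(mesh)
            assert st.enclosed_volume == pytest.approx(ref_vol, rel=0.02)
            vt, ft, _, _ = measure.marching_cubes(labp, level=-0.1)
            assert st.euler_characteristic == chi(vt, ft)

    def test_volume_error_shrinks_with_resolution(self):
        exact = 4 / 3 * np.pi * SPHERE_RADIUS ** 3
        errs = {}
        for n in (48, 96):
            st = mesh_stats(extract_surface(sphere_field(n)))
            errs[n] = abs(st.enclosed_volume - exact)
        assert errs[96] <= errs[48]


class TestVertexNormals:
    def test_two_sided_slab_normal_is_axis_aligned(self):
        # +1 for a <= 4, -1 for a >= 5: outward normal +x on the dividing plane
        labels = -np.ones((10, 9, 9), dtype=np.int8)
        labels[:5] = 1
        field = TriStateField(labels)
        mesh = vertex_normals(field, extract_surface(field))
        on_plane = np.isclose(mesh.vertices[:, 0], 4.5)
        interior = (np.abs(mesh.vertices[:, 1] - 4) < 2.5) & (np.abs(mesh.vertices[:, 2] - 4) < 2.5)
        sel = mesh.normals[on_plane & interior]
        assert len(sel) > 0
        assert np.allclose(sel, [1.0, 0.0, 0.0], atol=1e-12)

    def test_normals_are_unit(self, sphere_mesh_64_normals):
        mags = np.linalg.norm(sphere_mesh_64_normals.normals, axis=1)
        assert np.allclose(mags, 1.0, atol=1e-9)

    def test_sphere_normals_point_outward(self, sphere_mesh_64_normals):
        m = sphere_mesh_64_normals
        radial = m.vertices / np.linalg.norm(m.vertices, axis=1)[:, None]
        dots = np.einsum("ij,ij->i", m.normals, radial)
        assert (dots > 0).mean() >= 0.99
        angles = np.degrees(np.arccos(np.clip(dots, -1, 1)))
        assert np.median(angles) <= 30.0

    def test_constant_region_falls_back_to_face_normals(self, octa):
        # a mesh whose vertices lie on grid points of a *constant* field has
        # zero central differences everywhere: the fallback must still give
        # outward unit normals
        labels = np.ones((5, 5, 5), dtype=np.int8)
        field = TriStateField(labels)
        from ctsurf.core import TriMesh
        verts = octa.vertices * 2 + 2.0  # octahedron on integer grid points
        mesh = TriMesh(verts, octa.faces)
        out = vertex_normals(field, mesh)
        center = np.array([2.0, 2.0, 2.0])
        dots = np.einsum("ij,ij->i", out.normals, out.vertices - center)
        assert (dots > 0).all()

    def test_mismatched_mesh_rejected(self, sphere_field_64, octa):
        from ctsurf.core import TriMesh
        off = TriMesh(octa.vertices + 0.123, octa.faces)  # off the half-grid
        with pytest.raises(InvalidInputError):
            vertex_normals(sphere_field_64, off)


def test_watertight_for_interior_regions():
    """Any field whose inside region avoids the border yields a 2-manifold."""
    rng = np.random.default_rng(11)
    for _ in range(5):
        labels = -np.ones((9, 9, 9), dtype=np.int8)
        labels[2:7, 2:7, 2:7] = rng.choice([-1, 1], size=(5, 5, 5)).astype(np.int8)
        mesh = extract_surface(TriStateField(labels))
        if mesh.n_faces:
            assert mesh_stats(mesh).watertight
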