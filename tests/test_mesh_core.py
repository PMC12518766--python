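"""Unit and property tests for the mesh primitives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import cube_fan, flat_grid, icosphere, random_rotation, unit_cube
from spineforge.mesh_core import (
    MeshError,
    SmoothingParams,
    TriMesh,
    centroid,
    enclosed_volume,
    face_normals,
    fill_holes,
    laplacian_smooth,
    largest_component,
    point_in_mesh,
    remesh_isotropic,
    surface_area,
    tetrahedralize,
    vertex_normals,
    _compact,
)


class TestFaceNormals:
    @pytest.mark.parametrize(
        "tri, expected",
        [
            ([(0, 0, 0), (1, 0, 0), (0, 1, 0)], (0, 0, 1)),
            ([(0, 0, 0), (0, 1, 0), (1, 0, 0)], (0, 0, -1)),
        ],
    )
    def test_right_hand_rule(self, tri, expected):
        m = TriMesh(np.asarray(tri, dtype=float), np.array([[0, 1, 2]]))
        assert np.allclose(face_normals(m)[0], expected)

    def test_collinear_face_raises(self):
        m = TriMesh(np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2.0]]), np.array([[0, 1, 2]]))
        with pytest.raises(MeshError, match="degenerate"):
            face_normals(m)

    def test_unit_length_everywhere(self):
        m = icosphere(7.0, 3)
        n = np.linalg.norm(face_normals(m), axis=1)
        assert np.allclose(n, 1.0, atol=1e-12)


class TestVertexNormals:
    def test_icosphere_radial(self):
        m = icosphere(1.0, 3)
        vn = vertex_normals(m)
        radial = m.vertices / np.linalg.norm(m.vertices, axis=1, keepdims=True)
        assert np.abs(vn - radial).max() < 2e-2  # discretization error only
        # direction agreement is tight even where magnitude errs
        assert (np.einsum("ij,ij->i", vn, radial) > 1 - 1e-3).all()

    def test_flat_grid_interior_is_plus_z(self):
        g = flat_grid(5)
        vn = vertex_normals(g)
        assert np.allclose(vn, [0, 0, 1], atol=1e-12)

    def test_pyramid_apex_average(self):
        # symmetric square pyramid: apex normal is +z by symmetry, and equals
        # the normalized average of the four slant-face normals
        V = np.array(
            [[1, 1, 0], [-1, 1, 0], [-1, -1, 0], [1, -1, 0], [0, 0, 1.0]]
        )
        F = np.array([[0, 1, 4], [1, 2, 4], [2, 3, 4], [3, 0, 4]])
        m = TriMesh(V, F)
        assert np.allclose(vertex_normals(m)[4], [0, 0, 1], atol=1e-12)

    def test_isolated_vertex_raises(self):
        m = TriMesh(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [5, 5, 5.0]]), np.array([[0, 1, 2]]))
        with pytest.raises(MeshError, match="isolated"):
            vertex_normals(m)


class TestLaplacianSmooth:
    def _hex_cone(self):
        ring = [
            (np.cos(a), np.sin(a), 0.0) for a in np.linspace(0, 2 * np.pi, 6, endpoint=False)
        ]
        V = np.asarray([(0.0, 0.0, 1.0)] + ring)
        F = np.asarray([(0, 1 + i, 1 + (i + 1) % 6) for i in range(6)])
        return TriMesh(V, F)

    @pytest.mark.parametrize("lam, z_expected", [(1.0, 0.0), (0.5, 0.5)])
    def test_apex_moves_to_ring_centroid_blend(self, lam, z_expected):
        m = self._hex_cone()
        out = laplacian_smooth(m, SmoothingParams(lam, 1), subset=[0])
        assert np.allclose(out.vertices[0], [0, 0, z_expected], atol=1e-12)
        assert np.allclose(out.vertices[1:], m.vertices[1:])  # subset untouched

    def test_flat_grid_interior_fixed_point(self):
        g = flat_grid(5)
        interior = [i * 5 + j for i in range(1, 4) for j in range(1, 4)]
        out = laplacian_smooth(g, SmoothingParams(0.8, 7), subset=interior)
        assert np.abs(out.vertices - g.vertices).max() < 1e-12

    def test_connectivity_preserved_and_contractive(self):
        m = icosphere(5.0, 2)
        out = laplacian_smooth(m, SmoothingParams(0.7, 1))
        assert out.n_vertices == m.n_vertices
        assert np.array_equal(out.faces, m.faces)
        # displacement bounded by lam * distance to 1-ring centroid
        from spineforge.mesh_core import vertex_adjacency

        adj = vertex_adjacency(m)
        deg = np.asarray(adj.sum(axis=1)).ravel()
        cent = adj.dot(m.vertices) / deg[:, None]
        disp = np.linalg.norm(out.vertices - m.vertices, axis=1)
        bound = 0.7 * np.linalg.norm(cent - m.vertices, axis=1)
        assert np.all(disp <= bound + 1e-12)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            SmoothingParams(0.0, 1)
        with pytest.raises(ValueError):
            SmoothingParams(0.5, 0)


class TestCentroid:
    @pytest.mark.parametrize(
        "pts, expected",
        [
            ([(0, 0, 0), (1, 0, 0), (0, 1, 0)], (1 / 3, 1 / 3, 0)),
            ([(2.5, -1, 4)], (2.5, -1, 4)),
        ],
    )
    def test_examples(self, pts, expected):
        assert np.allclose(centroid(np.asarray(pts, dtype=float)), expected)

    def test_cube_corners(self):
        corners = np.array(np.meshgrid([0, 1], [0, 1], [0, 1])).T.reshape(-1, 3).astype(float)
        assert np.allclose(centroid(corners), [0.5, 0.5, 0.5])

    def test_empty_raises(self):
        with pytest.raises(MeshError):
            centroid(np.zeros((0, 3)))


class TestEnclosedVolume:
    def test_unit_cube(self):
        assert enclosed_volume(unit_cube()) == pytest.approx(1.0, abs=1e-12)

    def test_sphere_analytic(self):
        m = icosphere(10.0, 4)
        assert enclosed_volume(m) == pytest.approx(4 / 3 * np.pi * 1000, rel=0.01)

    def test_inverted_orientation_flips_sign(self):
        m = unit_cube()
        flipped = TriMesh(m.vertices, m.faces[:, ::-1])
        assert enclosed_volume(flipped) == pytest.approx(-enclosed_volume(m))

    def test_open_mesh_raises(self):
        m = unit_cube()
        open_m = TriMesh(m.vertices, m.faces[:-1])
        with pytest.raises(MeshError, match="boundary edges"):
            enclosed_volume(open_m)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_motion_invariance(self, seed):
        m = icosphere(6.0, 3)
        R = random_rotation(seed)
        v0 = enclosed_volume(m)
        v1 = enclosed_volume(m.transformed(R, (3.0, -7.0, 11.0)))
        assert abs(v1 - v0) / v0 < 1e-9


class TestLargestComponent:
    def test_strictly_larger_wins(self):
        sphere = icosphere(5.0, 2)
        blob = unit_cube().translated((20, 0, 0))
        both = TriMesh(
            np.vstack([sphere.vertices, blob.vertices]),
            np.vstack([sphere.faces, blob.faces + sphere.n_vertices]),
        )
        out = largest_component(both)
        assert out.n_faces == sphere.n_faces

    def test_single_component_identity(self):
        m = icosphere(5.0, 2)
        out = largest_component(m)
        assert out.n_faces == m.n_faces
        assert enclosed_volume(out) == pytest.approx(enclosed_volume(m))

    def test_tie_breaks_to_lowest_vertex_index(self):
        a = unit_cube()
        b = unit_cube().translated((10, 0, 0))
        both = TriMesh(
            np.vstack([a.vertices, b.vertices]), np.vstack([a.faces, b.faces + a.n_vertices])
        )
        out = largest_component(both)
        assert out.vertices[:, 0].max() <= 1.0  # the untranslated copy

    def test_empty_raises(self):
        with pytest.raises(MeshError):
            largest_component(TriMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int)))


class TestFillHoles:
    def _cube_missing_top(self):
        m = unit_cube()
        fn = face_normals(m)
        return _compact(m.vertices, m.faces[fn[:, 2] < 0.5])

    def test_fills_and_restores_euler_characteristic(self):
        holed = self._cube_missing_top()
        filled, skipped = fill_holes(holed, max_perimeter=10.0)
        assert skipped == 0
        assert filled.is_closed()
        chi = filled.n_vertices - len(filled.edges()) + filled.n_faces
        assert chi == 2
        assert enclosed_volume(filled) == pytest.approx(1.0, abs=1e-12)

    def test_closed_mesh_unchanged(self):
        m = unit_cube()
        out, skipped = fill_holes(m, 10.0)
        assert skipped == 0
        assert out.n_faces == m.n_faces

    def test_threshold_skips_large_loop(self):
        holed = self._cube_missing_top()
        out, skipped = fill_holes(holed, max_perimeter=0.1)
        assert skipped == 1
        assert out.n_faces == holed.n_faces


class TestPointInMesh:
    def test_center_and_outside(self):
        m = icosphere(1.0, 3)
        res = point_in_mesh(m, np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        assert res.tolist() == [True, False]

    def test_matches_analytic_sphere_membership(self):
        m = icosphere(1.0, 3)
        rng = np.random.default_rng(3)
        pts = rng.uniform(-2, 2, (1000, 3))
        r = np.linalg.norm(pts, axis=1)
        sag = 0.02  # facet sag of a subdiv-3 unit icosphere is ~6e-3
        clear = np.abs(r - 1.0) > sag
        res = point_in_mesh(m, pts)
        assert np.array_equal(res[clear], (r < 1.0)[clear])

    def test_matches_brute_force_ray_parity(self):
        m = icosphere(3.0, 2)  # 320 faces
        rng = np.random.default_rng(5)
        pts = rng.uniform(-4, 4, (1000, 3))
        res = point_in_mesh(m, pts)
        tri = m.triangles()
        # independent oracle: +x ray crossing parity, all faces, no grid
        expect = np.zeros(len(pts), dtype=bool)
        for i, p in enumerate(pts):
            a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
            d = (b[:, 2] - c[:, 2]) * (a[:, 1] - c[:, 1]) + (c[:, 1] - b[:, 1]) * (
                a[:, 2] - c[:, 2]
            )
            ok = np.abs(d) > 1e-14
            w1 = ((b[:, 2] - c[:, 2]) * (p[1] - c[:, 1]) + (c[:, 1] - b[:, 1]) * (p[2] - c[:, 2])) / np.where(ok, d, 1)
            w2 = ((c[:, 2] - a[:, 2]) * (p[1] - c[:, 1]) + (a[:, 1] - c[:, 1]) * (p[2] - c[:, 2])) / np.where(ok, d, 1)
            w3 = 1 - w1 - w2
            hit = ok & (w1 > 0) & (w2 > 0) & (w3 > 0)
            x_hit = w1[hit] * a[hit, 0] + w2[hit] * b[hit, 0] + w3[hit] * c[hit, 0]
            expect[i] = (x_hit > p[0]).sum() % 2 == 1
        assert np.array_equal(res, expect)

    def test_open_mesh_raises(self):
        m = unit_cube()
        with pytest.raises(MeshError):
            point_in_mesh(TriMesh(m.vertices, m.faces[:-1]), np.zeros((1, 3)))


class TestRemeshIsotropic:
    def test_refine_sphere_contract(self):
        m = icosphere(10.0, 3)
        out = remesh_isotropic(m, 1.0)
        e = out.edges(unique=True)
        med = np.median(np.linalg.norm(out.vertices[e[:, 0]] - out.vertices[e[:, 1]], axis=1))
        assert 0.75 <= med <= 1.25
        assert out.is_closed() and out.is_manifold()
        assert abs(enclosed_volume(out) - enclosed_volume(m)) / enclosed_volume(m) < 0.01

    def test_stability_at_current_median(self):
        m = icosphere(10.0, 3)
        e = m.edges(unique=True)
        med = np.median(np.linalg.norm(m.vertices[e[:, 0]] - m.vertices[e[:, 1]], axis=1))
        out = remesh_isotropic(m, float(med))
        assert 0.5 < out.n_faces / m.n_faces < 2.0

    def test_invalid_target_raises(self):
        with pytest.raises(MeshError):
            remesh_isotropic(icosphere(5.0, 2), -1.0)


class TestTetrahedralize:
    def test_cube_exact(self):
        t = tetrahedralize(unit_cube())
        assert t.volume() == pytest.approx(1.0, abs=1e-6)
        assert np.all(t.cell_volumes() > 0)

    def test_sphere_volume_consistency(self):
        m = icosphere(10.0, 3)
        t = tetrahedralize(m)
        assert t.volume() == pytest.approx(enclosed_volume(m), rel=1e-3)
        # boundary faces form a closed 2-cycle: every edge has even incidence
        bm = TriMesh(t.vertices, t.boundary_faces)
        _, counts = bm.edge_face_incidence()
        assert np.all(counts % 2 == 0)

    def test_open_surface_raises(self):
        m = icosphere(5.0, 2)
        with pytest.raises(MeshError):
            tetrahedralize(TriMesh(m.vertices, m.faces[:-1]))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    scale=st.floats(0.5, 3.0),
    tx=st.floats(-5, 5),
)
def test_volume_scales_cubically(scale, tx):
    """Enclosed volume is translation-invariant and scales as scale^3."""
    m = icosphere(2.0, 1)
    v0 = enclosed_volume(m)
    m2 = TriMesh(m.vertices * scale + np.array([tx, 0.0, 0.0]), m.faces)
    assert enclosed_volume(m2) == pytest.approx(v0 * scale**3, rel=1e-9)


def test_surface_area_sphere():
    m = icosphere(10.0, 4)
    assert surface_area(m) == pytest.approx(4 * np.pi * 100, rel=0.01)
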