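"""Ligament attachment: spherical planes, half-space selection, springs."""

import numpy as np
import pytest

from conftest import random_rotation, small_params, unit_cube
from spineforge.ligaments import (
    AttachmentPlane,
    LigamentSpec,
    SphericalCoordinate,
    attachment_region,
    build_ligament_springs,
    build_segment_springs,
    default_ligament_table,
    lf_midpoints,
    load_ligament_table,
    pll_attachment,
    save_ligament_table,
    select_attachment_vertices,
    spherical_to_cartesian,
    table_coordinates,
)
from spineforge.mesh_core import MeshError, TriMesh, centroid
from spineforge.synthetic_spine import make_vertebra


class TestSphericalToCartesian:
    @pytest.mark.parametrize(
        "coord, expected",
        [
            (SphericalCoordinate(0.0, 123.0, 1.0), (0, 0, 1)),
            (SphericalCoordinate(90.0, 0.0, 2.0), (2, 0, 0)),
        ],
    )
    def test_poles_and_equator(self, coord, expected):
        assert np.allclose(spherical_to_cartesian(coord), expected, atol=1e-12)

    def test_all_lower_row_trigonometry(self):
        # independent double-precision evaluation of the conversion for the
        # anterior-longitudinal lower attachment (29.063, -85, 18)
        n = spherical_to_cartesian(SphericalCoordinate(29.063, -85.0, 18.0))
        phi, th = np.radians(29.063), np.radians(-85.0)
        ref = 18.0 * np.array(
            [np.sin(phi) * np.cos(th), np.sin(phi) * np.sin(th), np.cos(phi)]
        )
        assert np.allclose(n, ref, atol=1e-12)
        assert np.allclose(n, [0.762, -8.711, 15.733], atol=2e-3)

    def test_negative_radius_reverses(self):
        c = SphericalCoordinate(40.0, 70.0, 3.0)
        assert np.allclose(
            spherical_to_cartesian(c),
            -spherical_to_cartesian(SphericalCoordinate(40.0, 70.0, -3.0)),
        )


class TestSelectAttachmentVertices:
    def test_cube_upper_half(self):
        m = unit_cube()  # centered at origin
        plane = AttachmentPlane(origin=np.zeros(3), normal=np.array([0.0, 0, 1]))
        sel = select_attachment_vertices(m, plane)
        assert len(sel) == 4
        assert np.all(m.vertices[sel][:, 2] > 0)

    def test_plane_above_cube_selects_none(self):
        m = unit_cube()
        plane = AttachmentPlane(origin=np.array([0.0, 0, 2]), normal=np.array([0.0, 0, 1]))
        with pytest.warns(UserWarning):
            sel = select_attachment_vertices(m, plane)
        assert len(sel) == 0

    def test_matches_brute_force_on_random_planes(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(200, 3)) * 5
        m = TriMesh(pts, np.array([[0, 1, 2]]))  # vertex cloud carrier
        for _ in range(100):
            o = rng.normal(size=3)
            n = rng.normal(size=3)
            sel = select_attachment_vertices(m, AttachmentPlane(o, n))
            brute = np.flatnonzero([(n @ (p - o)) > 0 for p in pts])
            assert np.array_equal(sel, brute)

    def test_zero_normal_raises(self):
        with pytest.raises(MeshError):
            AttachmentPlane(np.zeros(3), np.zeros(3))


class TestAttachmentRegion:
    def test_phi_zero_selects_superior_half(self):
        m = unit_cube()
        sel = attachment_region(m, np.zeros(3), SphericalCoordinate(0.0, 0.0, 1.0))
        assert np.all(m.vertices[sel][:, 2] > 0)

    def test_negative_radius_complementary(self):
        m = unit_cube()
        up = attachment_region(m, np.zeros(3), SphericalCoordinate(0.0, 0.0, 1.0))
        dn = attachment_region(m, np.zeros(3), SphericalCoordinate(0.0, 0.0, -1.0))
        assert len(np.intersect1d(up, dn)) == 0
        assert len(up) + len(dn) == 8  # no cube vertex lies on the plane

    def test_ssl_row_selects_posterior_on_vertebra(self):
        m = make_vertebra(small_params(), 2)
        c = centroid(m.vertices)
        sel = attachment_region(m, c, SphericalCoordinate(25.0, 90.7, -30.0))
        assert len(sel) > 0
        assert m.vertices[sel][:, 1].mean() < c[1]  # posterior = -y


class TestPLLAndLF:
    def test_single_closest_posterior(self):
        m = make_vertebra(small_params(), 1)
        c = centroid(m.vertices)
        sel = pll_attachment(m, c, 1)
        post = np.flatnonzero(m.vertices[:, 1] < c[1])
        d = np.linalg.norm(m.vertices[post] - c, axis=1)
        assert sel[0] == post[np.argmin(d)]

    def test_all_posterior_candidates(self):
        m = make_vertebra(small_params(), 1)
        c = centroid(m.vertices)
        post = np.flatnonzero(m.vertices[:, 1] < c[1])
        with pytest.warns(UserWarning):
            sel = pll_attachment(m, c, len(post) + 1000)
        assert np.array_equal(np.sort(sel), post)

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(500, 3)) * 10
        pts[:, 1] = -np.abs(pts[:, 1]) - 0.1  # all posterior of origin
        m = TriMesh(pts, np.array([[0, 1, 2]]))
        sel = pll_attachment(m, np.zeros(3), 20)
        d = np.linalg.norm(pts, axis=1)
        assert np.array_equal(np.sort(sel), np.sort(np.argsort(d, kind="stable")[:20]))

    def test_lf_midpoint_arithmetic_and_symmetry(self):
        a, b = np.array([0.0, 0, 0]), np.array([0.0, 0, 10])
        assert np.allclose(lf_midpoints(a, b), [0, 0, 5])
        assert np.allclose(lf_midpoints(a, b), lf_midpoints(b, a))
        with pytest.raises(MeshError):
            lf_midpoints(a, a)


class TestBuildLigamentSprings:
    def _patch(self, z, n=100, seed=0):
        rng = np.random.default_rng(seed)
        pts = np.column_stack([rng.uniform(-5, 5, (n, 2)), np.full(n, float(z))])
        return TriMesh(pts, np.array([[0, 1, 2]]))

    def test_parallel_patches_rest_length(self):
        up = self._patch(5.0)
        lo = self._patch(0.0)
        ss = build_ligament_springs(up, np.arange(100), lo, np.arange(100), 10)
        assert ss.n_springs == 10
        assert np.all(np.abs(ss.rest_lengths - 5.0) < 0.1)

    def test_single_spring_joins_centroid_nearest(self):
        up = self._patch(5.0)
        lo = self._patch(0.0)
        ss = build_ligament_springs(up, np.arange(100), lo, np.arange(100), 1)
        c = up.vertices.mean(axis=0)
        expect = int(np.argmin(np.linalg.norm(up.vertices - c, axis=1)))
        assert ss.nodes_upper[0] == expect

    def test_lower_singleton_shared_by_all(self):
        up = self._patch(5.0)
        lo = self._patch(0.0)
        ss = build_ligament_springs(up, np.arange(100), lo, np.array([3]), 10)
        assert np.all(ss.nodes_lower == 3)

    def test_empty_region_raises(self):
        up = self._patch(5.0)
        with pytest.raises(MeshError, match="empty"):
            build_ligament_springs(up, np.arange(100), up, np.array([], dtype=int), 10, ligament="ALL")


class TestDefaultTable:
    def test_row_count_and_springs(self):
        coords = table_coordinates()
        assert len(coords) == 11  # 9 plane rows + PLL + LF
        table = default_ligament_table()
        assert all(spec.n_springs == 10 for spec in table)

    def test_all_lower_coordinates(self):
        assert table_coordinates()["ALL_lower"] == (29.063, -85.0, 18.0)

    def test_plane_rows_values(self):
        c = table_coordinates()
        assert c["ALL_upper"] == (30.0, -85.0, -8.0)
        assert c["ITL_left"] == (35.0, 30.0, -1.0)
        assert c["ITL_right"] == (35.0, 156.0, -1.0)
        assert c["CL_lower_left"] == (25.0, 128.63, 16.0)
        assert c["CL_lower_right"] == (18.0, 61.0, 21.0)
        assert c["CL_upper_left"] == (-4.0, 30.0, -28.0)
        assert c["CL_upper_right"] == (-4.0, 140.0, -27.0)
        assert c["SSL_ISL"] == (25.0, 90.7, -30.0)
        assert c["PLL"] == "closest_n" and c["LF"] == "midpoint"

    def test_table_round_trip(self, tmp_path):
        table = default_ligament_table()
        for ext in ("json", "csv"):
            p = tmp_path / f"table.{ext}"
            save_ligament_table(table, p)
            back = load_ligament_table(p)
            assert [s.name for s in back] == [s.name for s in table]
            assert back[0].coord_lower.phi == table[0].coord_lower.phi


class TestSegmentSprings:
    def test_one_segment_inventory(self):
        p = small_params()
        v1, v2 = make_vertebra(p, 1), make_vertebra(p, 2)
        sets = build_segment_springs("L1", v1, "L2", v2)
        assert len(sets) == 8  # ALL, 2xITL, 2xCL, SSL/ISL, PLL, LF
        assert all(s.n_springs == 10 for s in sets)
        # every endpoint is an existing mesh vertex index
        for s in sets:
            assert s.nodes_upper.max() < v1.n_vertices
            assert s.nodes_lower.max() < v2.n_vertices
            assert np.all(s.rest_lengths > 0)

    @pytest.mark.parametrize("seed", [0])
    def test_selection_rotation_equivariance(self, seed):
        m = make_vertebra(small_params(), 3)
        c = centroid(m.vertices)
        R = random_rotation(seed)
        coord = SphericalCoordinate(25.0, 90.7, -30.0)
        sel0 = attachment_region(m, c, coord)
        # rotating mesh and plane normal together selects the same vertices
        mr = m.transformed(R)
        n = R @ spherical_to_cartesian(coord)
        sel1 = select_attachment_vertices(mr, AttachmentPlane(R @ c, n))
        assert np.array_equal(sel0, sel1)
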