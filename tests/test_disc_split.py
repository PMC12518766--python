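"""Nucleus/annulus separation tests with analytic cylinder oracles."""

import numpy as np
import pytest

from conftest import icosphere, random_rotation, small_params
from spineforge.disc_split import (
    BoundaryCurve,
    align_centroids,
    build_nucleus_solid,
    disc_boundary_curve,
    loft_walls,
    partition_disc_faces,
    pca_frame,
    scale_curve,
    split_disc,
    split_top_bottom,
)
from spineforge.mesh_core import MeshError, TriMesh, enclosed_volume, point_in_mesh
from spineforge.synthetic_spine import make_disc


def circular_cylinder(radius=10.0, height=10.0, n_az=64, n_ax=10, n_cap=5) -> TriMesh:
    """Closed right circular cylinder centered at the origin.

    Caps are tessellated with ``n_cap`` concentric rings so cap faces have
    realistic (locally uniform) size, like segmented anatomy.
    """
    th = np.arange(n_az) * 2 * np.pi / n_az
    cs = np.stack([np.cos(th), np.sin(th)], axis=1)

    rows = [
        np.column_stack([radius * cs, np.full(n_az, z)])
        for z in np.linspace(-height / 2, height / 2, n_ax)
    ]
    V = list(np.concatenate(rows))
    F = []
    for i in range(n_ax - 1):
        for j in range(n_az):
            a, b = i * n_az + j, i * n_az + (j + 1) % n_az
            c, d = (i + 1) * n_az + j, (i + 1) * n_az + (j + 1) % n_az
            F += [(a, b, d), (a, d, c)]

    def add_cap(rim_start: int, z: float, up: bool):
        nonlocal V, F
        prev = [rim_start + j for j in range(n_az)]
        for k in range(1, n_cap):
            rk = radius * (1 - k / n_cap)
            ring = [len(V) + j for j in range(n_az)]
            V.extend(np.column_stack([rk * cs, np.full(n_az, z)]))
            for j in range(n_az):
                a, b = prev[j], prev[(j + 1) % n_az]
                c, d = ring[j], ring[(j + 1) % n_az]
                if up:
                    F += [(a, b, d), (a, d, c)]
                else:
                    F += [(a, d, b), (a, c, d)]
            prev = ring
        ctr = len(V)
        V.append(np.array([0.0, 0.0, z]))
        for j in range(n_az):
            a, b = prev[j], prev[(j + 1) % n_az]
            F.append((a, b, ctr) if up else (a, ctr, b))

    add_cap((n_ax - 1) * n_az, height / 2, up=True)
    add_cap(0, -height / 2, up=False)
    return TriMesh(np.asarray(V), np.asarray(F, dtype=np.int64))


class TestPCAFrame:
    def test_planar_cloud_degenerate_axis(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.normal(size=(200, 2)), np.zeros(200)])
        f = pca_frame(pts)
        assert abs(abs(f.u3[2]) - 1.0) < 1e-10
        assert f.variances[2] == pytest.approx(0.0, abs=1e-12)

    def test_recovers_generation_axes(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10000, 3)) * np.array([3.0, 2.0, 0.5])
        f = pca_frame(pts)
        for u, e in zip((f.u1, f.u2, f.u3), np.eye(3)):
            ang = np.degrees(np.arccos(np.clip(abs(u @ e), 0, 1)))
            assert ang < 3.0

    def test_collinear_points_rank_one(self):
        # rank deficiency allowed: u1 along the segment, both other variances zero
        pts = np.array([[0.0, 0, 0], [1.0, 1, 1], [2.0, 2, 2]])
        f = pca_frame(pts, anterior=(1, 1, 1))
        assert f.variances[1] == pytest.approx(0.0, abs=1e-12)
        assert f.variances[2] == pytest.approx(0.0, abs=1e-12)
        assert abs(f.u1 @ (np.ones(3) / np.sqrt(3))) == pytest.approx(1.0)

    def test_fewer_than_three_points_raises(self):
        with pytest.raises(MeshError):
            pca_frame(np.array([[0.0, 0, 0], [1.0, 1, 1]]))

    def test_unbiased_covariance_normalization(self):
        pts = np.array([[0.0, 0, 0], [2.0, 0, 0], [0.0, 2, 0], [2.0, 2, 0]])
        f = pca_frame(pts)
        # var along x and y with 1/(n-1): 4/3
        assert f.variances[0] == pytest.approx(4 / 3)

    def test_axes_right_handed_orthonormal(self):
        rng = np.random.default_rng(2)
        f = pca_frame(rng.normal(size=(50, 3)))
        assert np.allclose(f.axes @ f.axes.T, np.eye(3), atol=1e-10)
        assert np.linalg.det(f.axes) > 0

    def test_too_few_points_raises(self):
        with pytest.raises(MeshError):
            pca_frame(np.zeros((2, 3)))


class TestBoundaryCurve:
    def test_elliptical_perimeter_matches_ramanujan(self):
        d = make_disc(small_params(), 1)
        f = pca_frame(d.vertices)
        curve = disc_boundary_curve(d, f, 64)
        a, b = small_params().disc_radii
        h = ((a - b) / (a + b)) ** 2
        peri = np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
        assert curve.perimeter() == pytest.approx(peri, rel=0.02)

    def test_circular_cylinder_radius(self):
        cyl = circular_cylinder(radius=7.0)
        f = pca_frame(cyl.vertices)
        curve = disc_boundary_curve(cyl, f, 64)
        r = np.linalg.norm(curve.plane_coords() - curve.plane_coords().mean(axis=0), axis=1)
        assert np.all(np.abs(r - 7.0) / 7.0 < 0.02)

    def test_resampling_count_and_equal_arcs(self):
        cyl = circular_cylinder()
        f = pca_frame(cyl.vertices)
        curve = disc_boundary_curve(cyl, f, 64)
        assert len(curve.points) == 64
        seg = np.linalg.norm(np.roll(curve.points, -1, axis=0) - curve.points, axis=1)
        assert seg.max() / seg.min() < 1.01


class TestScaleCurve:
    def _circle(self, n=32):
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        pts = np.stack([np.cos(th), np.sin(th), np.zeros(n)], axis=1)
        f = pca_frame(pts + np.random.default_rng(0).normal(scale=0, size=pts.shape))
        return BoundaryCurve(pts, f)

    def test_identity_at_one(self):
        c = self._circle()
        out = scale_curve(c, 1.0)
        assert np.allclose(out.points, c.points)

    def test_half_scale_halves_radius(self):
        c = self._circle()
        out = scale_curve(c, 0.5)
        r = np.linalg.norm(out.points - out.points.mean(axis=0), axis=1)
        assert np.allclose(r, 0.5, atol=1e-12)

    def test_perimeter_scales_linearly(self):
        d = make_disc(small_params(), 2)
        f = pca_frame(d.vertices)
        curve = disc_boundary_curve(d, f, 48)
        out = scale_curve(curve, 0.6)
        assert out.perimeter() == pytest.approx(0.6 * curve.perimeter(), rel=1e-9)

    @pytest.mark.parametrize("s", [0.0, -0.5, 1.5])
    def test_invalid_scale_raises(self, s):
        with pytest.raises(MeshError):
            scale_curve(self._circle(), s)


class TestBuildNucleusSolid:
    def test_clipped_cylinder_volume(self):
        cyl = circular_cylinder(radius=10.0, height=10.0)
        f = pca_frame(cyl.vertices)
        curve = scale_curve(disc_boundary_curve(cyl, f, 64), 0.5)
        nuc = build_nucleus_solid(curve, cyl, point_spacing=1.0)
        assert enclosed_volume(nuc) == pytest.approx(np.pi * 25 * 10, rel=0.05)

    def test_full_scale_recovers_disc_volume(self):
        cyl = circular_cylinder(radius=10.0, height=10.0)
        f = pca_frame(cyl.vertices)
        curve = disc_boundary_curve(cyl, f, 64)
        nuc = build_nucleus_solid(curve, cyl, point_spacing=1.0)
        assert enclosed_volume(nuc) == pytest.approx(enclosed_volume(cyl), rel=0.08)

    def test_conforming_vertices_inside_disc(self):
        d = make_disc(small_params(), 1)
        f = pca_frame(d.vertices)
        curve = scale_curve(disc_boundary_curve(d, f, 48), 0.6)
        nuc = build_nucleus_solid(curve, d, point_spacing=1.5)
        from spineforge.mesh_core import distance_to_mesh

        inside = point_in_mesh(d, nuc.vertices)
        dist = distance_to_mesh(d, nuc.vertices)
        assert np.all(inside | (dist < 1e-6))


class TestAlignCentroids:
    def test_already_centered_is_identity(self):
        m = icosphere(2.0, 1)
        out = align_centroids(m, m)
        assert np.allclose(out.vertices, m.vertices)

    def test_translation_recovered(self):
        m = icosphere(2.0, 1)
        shifted = m.translated((1.0, 2.0, 3.0))
        out = align_centroids(shifted, m)
        assert np.allclose(out.vertices, m.vertices, atol=1e-12)

    def test_rigid_shape_preserving(self):
        m = icosphere(2.0, 1)
        out = align_centroids(m, m.translated((5, 0, 0)))
        d0 = np.linalg.norm(m.vertices[0] - m.vertices[7])
        d1 = np.linalg.norm(out.vertices[0] - out.vertices[7])
        assert d0 == pytest.approx(d1, abs=1e-12)


class TestPartitionDiscFaces:
    def test_enclosing_nucleus_takes_all(self):
        d = icosphere(1.0, 2)
        big = icosphere(5.0, 2)
        ann, nuc = partition_disc_faces(d, big)
        assert len(ann) == 0 and len(nuc) == d.n_faces

    def test_distant_nucleus_takes_none(self):
        d = icosphere(1.0, 2)
        far = icosphere(1.0, 2).translated((10, 0, 0))
        ann, nuc = partition_disc_faces(d, far)
        assert len(nuc) == 0 and len(ann) == d.n_faces

    def test_concentric_smaller_sphere_all_annulus(self):
        d = icosphere(1.0, 2)
        inner = icosphere(0.5, 2)
        ann, nuc = partition_disc_faces(d, inner)
        assert len(nuc) == 0 and len(ann) == d.n_faces

    def test_partition_exhaustive_exclusive(self):
        d = make_disc(small_params(), 1)
        part = split_disc(d, tetrahedralize_parts=False)
        assert len(part.annulus_faces) + len(part.nucleus_faces) == d.n_faces
        assert len(np.intersect1d(part.annulus_faces, part.nucleus_faces)) == 0


class TestSplitTopBottom:
    @pytest.mark.parametrize("zs", [(0.0, 10.0), (-4.0, 4.0)])
    def test_threshold_is_mid_range(self, zs):
        # two horizontal triangles at the given heights
        V = np.array(
            [[0, 0, zs[0]], [1, 0, zs[0]], [0, 1, zs[0]], [0, 0, zs[1]], [1, 0, zs[1]], [0, 1, zs[1]]],
            dtype=float,
        )
        F = np.array([[0, 1, 2], [3, 4, 5]])
        m = TriMesh(V, F)
        f = pca_frame(np.vstack([V, V + [5, 5, 0]]))  # frame with u3 ~ +z
        top, bottom, thr = split_top_bottom(m, np.arange(2), f)
        z_f = (V[F].mean(axis=1) - f.mean) @ f.u3
        assert thr == pytest.approx(0.5 * (z_f.max() + z_f.min()), abs=1e-9)
        assert len(top) == 1 and len(bottom) == 1

    def test_cylinder_caps_separate(self):
        cyl = circular_cylinder(radius=5.0, height=10.0, n_az=24, n_ax=5)
        f = pca_frame(cyl.vertices)
        cent_z = cyl.vertices[cyl.faces].mean(axis=1) @ f.u3
        top, bottom, thr = split_top_bottom(cyl, np.arange(cyl.n_faces), f)
        assert np.all(cent_z[np.isin(np.arange(cyl.n_faces), top)] > thr + f.mean @ f.u3 - 1e-9)


class TestLoftWalls:
    def _circle_curve(self, z, n=32, rot=0):
        th = np.arange(n) * 2 * np.pi / n + rot
        pts = np.stack([np.cos(th), np.sin(th), np.full(n, float(z))], axis=1)
        f = pca_frame(np.vstack([pts, pts + [0, 0, 1]]))
        return BoundaryCurve(pts, f)

    def test_triangle_count_is_2n(self):
        w = loft_walls(self._circle_curve(1.0), self._circle_curve(0.0))
        assert w.n_faces == 64

    def test_identical_curves_degenerate(self):
        with pytest.raises(MeshError, match="degenerate"):
            loft_walls(self._circle_curve(0.0), self._circle_curve(0.0))

    def test_cyclic_shift_alignment_invariance(self):
        top = self._circle_curve(1.0)
        w0 = loft_walls(top, self._circle_curve(0.0))
        shifted = self._circle_curve(0.0)
        shifted = BoundaryCurve(np.roll(shifted.points, 5, axis=0), shifted.frame)
        w1 = loft_walls(top, shifted)
        from spineforge.mesh_core import surface_area

        assert surface_area(w0) == pytest.approx(surface_area(w1), abs=1e-9)

    def test_count_mismatch_raises(self):
        with pytest.raises(MeshError, match="differ"):
            loft_walls(self._circle_curve(1.0, n=32), self._circle_curve(0.0, n=16))


class TestStitchEndToEnd:
    def test_volume_conservation_on_cylinder(self):
        cyl = circular_cylinder(radius=10.0, height=10.0)
        part = split_disc(cyl)
        vd = enclosed_volume(cyl)
        vsum = part.nucleus_solid.volume() + part.annulus_solid.volume()
        assert abs(vsum - vd) / vd < 0.03

    def test_outputs_watertight(self):
        d = make_disc(small_params(), 3)
        part = split_disc(d, tetrahedralize_parts=False)
        assert part.nucleus_mesh.is_closed()
        assert part.annulus_mesh.is_closed()

    def test_interface_nodes_shared_bitwise(self):
        d = make_disc(small_params(), 1)
        part = split_disc(d, tetrahedralize_parts=False)
        nuc = {tuple(v) for v in part.nucleus_mesh.vertices}
        ann = {tuple(v) for v in part.annulus_mesh.vertices}
        # the wall rim vertices appear in both surfaces with identical coords
        assert len(nuc & ann) > 0

    def test_scaling_monotonicity(self):
        d = make_disc(small_params(), 2)
        vols = [
            enclosed_volume(split_disc(d, scale=s, tetrahedralize_parts=False).nucleus_mesh)
            for s in (0.4, 0.6, 0.8)
        ]
        assert vols[0] < vols[1] < vols[2]

    @pytest.mark.parametrize("seed", [0])
    def test_rotation_equivariance(self, seed):
        d = make_disc(small_params(), 1)
        R = random_rotation(seed)
        sup = R @ np.array([0.0, 0.0, 1.0])
        ant = R @ np.array([0.0, 1.0, 0.0])
        a = split_disc(d, tetrahedralize_parts=False)
        b = split_disc(d.transformed(R), superior=sup, anterior=ant, tetrahedralize_parts=False)
        assert np.array_equal(np.sort(a.nucleus_faces), np.sort(b.nucleus_faces))
        va = np.sort(np.linalg.norm(a.nucleus_mesh.vertices - a.nucleus_mesh.vertices.mean(0), axis=1))
        vb = np.sort(np.linalg.norm(b.nucleus_mesh.vertices - b.nucleus_mesh.vertices.mean(0), axis=1))
        assert np.abs(va - vb).max() < 1e-6
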