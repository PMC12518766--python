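"""Nucleus / annulus separation of an intervertebral disc.

The disc's intrinsic orientation comes from PCA of its vertices: the two
largest-variance axes span the transverse plane, the smallest-variance axis
is the disc's own stacking axis.  The disc outline is projected onto the PCA
plane, shrunk by a user-set scale factor to define the nucleus footprint,
extruded through the disc and clipped to its interior; disc surface faces are
then classified against that nucleus solid (a face belongs to the nucleus as
soon as one of its vertices is inside), the nucleus patch is split into top
and bottom caps by the mid z-threshold, and a lofted wall closes both the
nucleus and the annulus into watertight solids that share the interface
geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay

from .mesh_core import (
    MeshError,
    TetMesh,
    TriMesh,
    _compact,
    boundary_loops,
    centroid,
    enclosed_volume,
    fill_holes,
    orient_consistently,
    point_in_mesh,
    ray_mesh_first_hit,
    tetrahedralize,
)

DEFAULT_NUCLEUS_SCALE = 0.6  # nucleus cross-section ~36% of disc area
EXTRUSION_MARGIN = 0.05  # fraction of the disc's axial extent


# ---------------------------------------------------------------------------
# PCA frame
# ---------------------------------------------------------------------------


@dataclass
class PCAFrame:
    """Mean point plus orthonormal right-handed principal axes (desc. variance)."""

    mean: np.ndarray
    axes: np.ndarray  # rows u1, u2, u3
    variances: np.ndarray  # lam1 >= lam2 >= lam3 >= 0

    @property
    def u1(self) -> np.ndarray:
        return self.axes[0]

    @property
    def u2(self) -> np.ndarray:
        return self.axes[1]

    @property
    def u3(self) -> np.ndarray:
        return self.axes[2]

    def to_plane(self, points: np.ndarray) -> np.ndarray:
        """(u1, u2) coordinates of points relative to the mean."""
        return (np.asarray(points, dtype=float) - self.mean) @ self.axes[:2].T

    def axial(self, points: np.ndarray) -> np.ndarray:
        """Signed u3 coordinate relative to the mean."""
        return (np.asarray(points, dtype=float) - self.mean) @ self.u3

    def from_plane(self, xy: np.ndarray, t=0.0) -> np.ndarray:
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        t = np.broadcast_to(np.asarray(t, dtype=float), len(xy))
        return self.mean + xy[:, :1] * self.u1 + xy[:, 1:2] * self.u2 + t[:, None] * self.u3


def pca_frame(
    points: np.ndarray,
    superior=(0.0, 0.0, 1.0),
    anterior=(0.0, 1.0, 0.0),
) -> PCAFrame:
    """Principal axes of a point cloud with deterministic sign/tie conventions.

    Covariance uses the unbiased 1/(n-1) normalization.  Eigenvector signs are
    fixed so u3 points toward ``superior`` and u1 toward ``anterior``; u2
    completes a right-handed frame.  Eigenvalue ties resolve by preferring the
    most superior-aligned axis as u3 (then the most anterior-aligned as u1).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 3:
        raise MeshError("pca_frame requires at least 3 points")
    mean = pts.mean(axis=0)
    cov = (pts - mean).T @ (pts - mean) / (len(pts) - 1)
    lam, U = np.linalg.eigh(cov)  # ascending
    lam = lam[::-1].copy()
    U = U[:, ::-1].copy()  # columns u1, u2, u3 by descending variance
    lam = np.maximum(lam, 0.0)
    sup = np.asarray(superior, dtype=float)
    sup = sup / np.linalg.norm(sup)
    ant = np.asarray(anterior, dtype=float)
    ant = ant / np.linalg.norm(ant)
    tol = 1e-6 * max(lam[0], 1e-30)
    # ties: within a degenerate eigen-subspace any basis is an eigenbasis, so
    # project the reference direction onto the tied subspace — deterministic
    # and exactly axis-aligned for isotropic clouds
    tied_low = [2] + [k for k in (1, 0) if abs(lam[k] - lam[2]) <= tol]
    if len(tied_low) > 1:
        B = U[:, tied_low]
        w = B @ (B.T @ sup)
        n = np.linalg.norm(w)
        u3 = w / n if n > 1e-12 else U[:, 2]
    else:
        u3 = U[:, 2]
    if u3 @ sup < 0:
        u3 = -u3
    lam3 = lam[2]
    if len(tied_low) == 3:
        a_perp = ant - (ant @ u3) * u3
        n = np.linalg.norm(a_perp)
        u1 = a_perp / n if n > 1e-12 else _any_perp(u3)
        lam1 = lam2 = lam[0]
    else:
        if abs(lam[0] - lam[1]) <= tol:
            # top pair tied: orient within its span toward anterior
            B = U[:, [0, 1]]
            w = B @ (B.T @ ant)
            w = w - (w @ u3) * u3
            n = np.linalg.norm(w)
            u1 = w / n if n > 1e-12 else U[:, 0]
        else:
            u1 = U[:, 0] - (U[:, 0] @ u3) * u3
            u1 = u1 / np.linalg.norm(u1)
        if u1 @ ant < 0:
            u1 = -u1
        lam1, lam2 = lam[0], lam[1]
    u2 = np.cross(u3, u1)
    return PCAFrame(mean=mean, axes=np.stack([u1, u2, u3]), variances=np.array([lam1, lam2, lam3]))


def _any_perp(u: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    w = np.cross(u, ref)
    return w / np.linalg.norm(w)


# ---------------------------------------------------------------------------
# boundary curve
# ---------------------------------------------------------------------------


@dataclass
class BoundaryCurve:
    """Ordered closed polyline (implicit closure) in a PCA frame's plane."""

    points: np.ndarray  # (n, 3)
    frame: PCAFrame

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 3:
            raise MeshError("a boundary curve needs at least 3 points")

    def plane_coords(self) -> np.ndarray:
        return self.frame.to_plane(self.points)

    def perimeter(self) -> float:
        p = self.points
        return float(np.linalg.norm(np.roll(p, -1, axis=0) - p, axis=1).sum())

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


def _resample_closed(xy: np.ndarray, n: int) -> np.ndarray:
    """Equal-arc-length resampling of a closed 2D polyline."""
    seg = np.linalg.norm(np.roll(xy, -1, axis=0) - xy, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    s = np.arange(n) * total / n
    idx = np.searchsorted(cum, s, side="right") - 1
    idx = np.clip(idx, 0, len(xy) - 1)
    denom = np.where(seg[idx] > 0, seg[idx], 1.0)
    t = (s - cum[idx]) / denom
    nxt = (idx + 1) % len(xy)
    return xy[idx] + t[:, None] * (xy[nxt] - xy[idx])


def _alpha_boundary(xy: np.ndarray, alpha: float) -> np.ndarray | None:
    """Longest boundary loop of the 2D alpha complex (circumradius < alpha)."""
    if len(xy) < 4:
        return None
    try:
        dela = Delaunay(xy)
    except Exception:
        return None
    tri = dela.simplices
    p = xy[tri]
    a = np.linalg.norm(p[:, 1] - p[:, 0], axis=1)
    b = np.linalg.norm(p[:, 2] - p[:, 1], axis=1)
    c = np.linalg.norm(p[:, 0] - p[:, 2], axis=1)
    s = 0.5 * (a + b + c)
    area = np.sqrt(np.maximum(s * (s - a) * (s - b) * (s - c), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        circ = np.where(area > 1e-14, a * b * c / (4.0 * area), np.inf)
    keep = tri[circ < alpha]
    if len(keep) == 0:
        return None
    edges = np.sort(
        np.concatenate([keep[:, [0, 1]], keep[:, [1, 2]], keep[:, [2, 0]]]), axis=1
    )
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    be = uniq[counts == 1]
    if len(be) < 3:
        return None
    nbr: dict[int, list[int]] = {}
    for u, v in be:
        nbr.setdefault(int(u), []).append(int(v))
        nbr.setdefault(int(v), []).append(int(u))
    if any(len(v) != 2 for v in nbr.values()):
        return None  # pinched alpha complex; fall back to the convex hull
    best = None
    seen: set[int] = set()
    for start in nbr:
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur, prev = start, None
        while True:
            nxts = [x for x in nbr[cur] if x != prev]
            if not nxts:
                break
            nxt = nxts[0]
            if nxt == start:
                break
            loop.append(nxt)
            seen.add(nxt)
            prev, cur = cur, nxt
        pts = xy[loop]
        per = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1).sum()
        if best is None or per > best[0]:
            best = (per, np.asarray(loop))
    return best[1] if best is not None else None


def disc_boundary_curve(disc: TriMesh, frame: PCAFrame, n_samples: int = 64) -> BoundaryCurve:
    """Outer outline of the disc projected onto the PCA plane.

    Concave hull via a 2D alpha shape (alpha = 2x the median mesh edge
    length), convex-hull fallback, resampled to ``n_samples`` points at equal
    arc length.  The curve starts at its most anterior (max u1) point and runs
    counter-clockwise in the (u1, u2) plane.
    """
    if n_samples < 8:
        raise MeshError("n_samples must be >= 8")
    if frame.variances[1] <= 1e-12:
        raise MeshError("degenerate projection: second principal variance is zero")
    xy = frame.to_plane(disc.vertices)
    e = disc.edges(unique=True)
    med_edge = float(np.median(np.linalg.norm(disc.vertices[e[:, 0]] - disc.vertices[e[:, 1]], axis=1)))
    loop = _alpha_boundary(xy, alpha=2.0 * med_edge)
    if loop is None:
        from scipy.spatial import ConvexHull

        loop = ConvexHull(xy).vertices
    pts2 = xy[loop]
    # orient counter-clockwise (positive shoelace area)
    area2 = float(np.sum(pts2[:, 0] * np.roll(pts2[:, 1], -1) - np.roll(pts2[:, 0], -1) * pts2[:, 1]))
    if area2 < 0:
        pts2 = pts2[::-1]
    start = int(np.argmax(pts2[:, 0]))
    pts2 = np.roll(pts2, -start, axis=0)
    res = _resample_closed(pts2, n_samples)
    return BoundaryCurve(points=frame.from_plane(res), frame=frame)


def scale_curve(curve: BoundaryCurve, s: float) -> BoundaryCurve:
    """Similarity-shrink the curve about its centroid: p -> c + s (p - c)."""
    if not (0.0 < s <= 1.0):
        raise MeshError(f"scale factor must be in (0, 1], got {s}")
    c = curve.centroid()
    return BoundaryCurve(points=c + s * (curve.points - c), frame=curve.frame)


# ---------------------------------------------------------------------------
# nucleus solid
# ---------------------------------------------------------------------------


def build_nucleus_solid(
    curve: BoundaryCurve, disc: TriMesh, point_spacing: float = 1.0, conform: bool = True
) -> TriMesh:
    """Extrude the scaled footprint through the disc and clip to its interior.

    The footprint is swept along the frame's u3 axis across the disc's axial
    extent (plus a 5% margin).  With ``conform`` (default) the extrusion is
    clipped against the disc by casting axial rays at each footprint sample,
    so the caps conform to the disc's top/bottom surfaces; with
    ``conform=False`` the raw capped extrusion is returned, which is the
    robust classification solid (it strictly contains the disc surface above
    and below the footprint).  Output is closed either way.
    """
    frame = curve.frame
    xy_b = curve.plane_coords()
    c2d = xy_b.mean(axis=0)
    per = curve.perimeter()
    n_az = max(16, int(np.ceil(per / point_spacing)))
    xy_b = _resample_closed(xy_b, n_az)
    t_all = frame.axial(disc.vertices)
    t_lo, t_hi = float(t_all.min()), float(t_all.max())
    margin = EXTRUSION_MARGIN * (t_hi - t_lo)
    mean_r = float(np.mean(np.linalg.norm(xy_b - c2d, axis=1)))
    n_rad = max(2, int(np.ceil(mean_r / point_spacing)))
    # concentric rings from the footprint boundary (k=0) toward the centre
    scales = 1.0 - np.arange(n_rad) / n_rad  # 1 .. >0
    ring_xy = [c2d + (s * (1.0 - 1e-9)) * (xy_b - c2d) for s in scales]
    samples = np.concatenate(ring_xy + [c2d[None, :]])
    if conform:
        origins_lo = frame.from_plane(samples, t_lo - margin - 1.0)
        origins_hi = frame.from_plane(samples, t_hi + margin + 1.0)
        d_lo = ray_mesh_first_hit(disc, origins_lo, np.tile(frame.u3, (len(samples), 1)))
        d_hi = ray_mesh_first_hit(disc, origins_hi, np.tile(-frame.u3, (len(samples), 1)))
        if not np.all(np.isfinite(d_lo)) or not np.all(np.isfinite(d_hi)):
            miss = np.flatnonzero(~np.isfinite(d_lo) | ~np.isfinite(d_hi))
            raise MeshError(
                f"nucleus footprint does not intersect the disc at {len(miss)} samples"
            )
        t_bot = (t_lo - margin - 1.0) + d_lo
        t_top = (t_hi + margin + 1.0) - d_hi
        if np.any(t_top <= t_bot + 1e-9):
            raise MeshError("empty axial intersection between extrusion and disc")
    else:
        t_bot = np.full(len(samples), t_lo - margin)
        t_top = np.full(len(samples), t_hi + margin)
    top_v = frame.from_plane(samples, t_top)
    bot_v = frame.from_plane(samples, t_bot)
    nv_cap = len(samples)
    V = np.concatenate([top_v, bot_v])  # top cap block, bottom cap block

    def cap_faces(offset: int, up: bool) -> list[tuple[int, int, int]]:
        faces = []
        for k in range(n_rad - 1):
            r0, r1 = k * n_az, (k + 1) * n_az
            for j in range(n_az):
                a = offset + r0 + j
                b = offset + r0 + (j + 1) % n_az
                c = offset + r1 + j
                d = offset + r1 + (j + 1) % n_az
                if up:
                    faces += [(a, d, b), (a, c, d)]
                else:
                    faces += [(a, b, d), (a, d, c)]
        ctr = offset + n_rad * n_az
        r_last = (n_rad - 1) * n_az
        for j in range(n_az):
            a = offset + r_last + j
            b = offset + r_last + (j + 1) % n_az
            faces.append((a, ctr, b) if up else (a, b, ctr))
        return faces

    F = cap_faces(0, up=True) + cap_faces(nv_cap, up=False)
    for j in range(n_az):  # lateral wall between the two boundary rings
        a, b = j, (j + 1) % n_az
        a2, b2 = nv_cap + a, nv_cap + b
        F += [(a, b, b2), (a, b2, a2)]
    out = TriMesh(V, np.asarray(F, dtype=np.int64)).clean()
    out = orient_consistently(out, outward=True)
    if not out.is_closed():
        raise MeshError("nucleus solid construction produced an open mesh")
    return out


def align_centroids(nucleus: TriMesh, annulus_ref: TriMesh) -> TriMesh:
    """Translate the nucleus so its vertex centroid matches the reference's."""
    t = centroid(annulus_ref.vertices) - centroid(nucleus.vertices)
    return nucleus.translated(t)


# ---------------------------------------------------------------------------
# face partition + stitching
# ---------------------------------------------------------------------------


def partition_disc_faces(disc: TriMesh, nucleus: TriMesh) -> tuple[np.ndarray, np.ndarray]:
    """Split disc face indices into (annulus, nucleus) sets.

    A face is a nucleus face iff at least one of its vertices lies inside the
    nucleus solid; otherwise it is an annulus face.  Exhaustive and exclusive.
    """
    inside = point_in_mesh(nucleus, disc.vertices)
    face_in = inside[disc.faces].any(axis=1)
    return np.flatnonzero(~face_in), np.flatnonzero(face_in)


def split_top_bottom(
    mesh: TriMesh, face_indices: np.ndarray, frame: PCAFrame
) -> tuple[np.ndarray, np.ndarray, float]:
    """Split faces into top/bottom by the mean of min/max axial centroid height."""
    face_indices = np.asarray(face_indices, dtype=np.int64)
    if len(face_indices) == 0:
        raise MeshError("empty face set")
    cent = mesh.vertices[mesh.faces[face_indices]].mean(axis=1)
    z = (cent - frame.mean) @ frame.u3
    thr = 0.5 * (float(z.max()) + float(z.min()))
    top = face_indices[z > thr]
    bottom = face_indices[z <= thr]
    return top, bottom, thr


def loft_walls(top_boundary: BoundaryCurve, bottom_boundary: BoundaryCurve) -> TriMesh:
    """Triangulated wall between two equal-count closed curves.

    Correspondence is the cyclic shift (optionally with direction reversal) of
    the bottom curve minimizing the total squared distance; each of the N
    corresponded quads splits into 2 triangles.
    """
    a = top_boundary.points
    b = bottom_boundary.points
    if len(a) != len(b):
        raise MeshError(f"curve sample counts differ: {len(a)} vs {len(b)}")
    n = len(a)
    best = None
    for rev in (False, True):
        bb = b[::-1] if rev else b
        for s in range(n):
            d = float(((a - np.roll(bb, -s, axis=0)) ** 2).sum())
            if best is None or d < best[0]:
                best = (d, rev, s)
    _, rev, s = best
    bb = np.roll(b[::-1] if rev else b, -s, axis=0)
    V = np.concatenate([a, bb])
    F = []
    for i in range(n):
        j = (i + 1) % n
        F += [(i, j, n + j), (i, n + j, n + i)]
    out = TriMesh(V, np.asarray(F, dtype=np.int64))
    if np.any(out.face_areas() < 1e-10):
        raise MeshError("degenerate loft: curves too close (zero-area triangles)")
    return out


def _zipper_loops(
    vertices: np.ndarray, loop_a: np.ndarray, loop_b: np.ndarray
) -> np.ndarray:
    """Greedy minimal-edge triangulation between two closed vertex loops.

    Returns faces indexing into ``vertices``.  Both loops may have different
    lengths; they are first oriented consistently and started at the closest
    vertex pair.
    """
    pa, pb = vertices[loop_a], vertices[loop_b]
    # orient loop_b to run the same way as loop_a around their common axis
    ca, cb = pa.mean(axis=0), pb.mean(axis=0)
    axis = ca - cb
    nrm = np.linalg.norm(axis)
    axis = axis / nrm if nrm > 1e-12 else np.array([0.0, 0.0, 1.0])

    def signed_area(pts, ctr):
        ref = np.asarray([1.0, 0.0, 0.0])
        if abs(ref @ axis) > 0.9:
            ref = np.asarray([0.0, 1.0, 0.0])
        e1 = np.cross(axis, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(axis, e1)
        q = np.stack([(pts - ctr) @ e1, (pts - ctr) @ e2], axis=1)
        return float(np.sum(q[:, 0] * np.roll(q[:, 1], -1) - np.roll(q[:, 0], -1) * q[:, 1]))

    if signed_area(pa, ca) * signed_area(pb, cb) < 0:
        loop_b = loop_b[::-1]
        pb = vertices[loop_b]
    # start both loops at the globally closest pair
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    ia, ib = np.unravel_index(int(np.argmin(d)), d.shape)
    loop_a = np.roll(loop_a, -ia)
    loop_b = np.roll(loop_b, -ib)
    pa, pb = vertices[loop_a], vertices[loop_b]
    na, nb = len(loop_a), len(loop_b)

    def _params(p):
        seg = np.linalg.norm(np.roll(p, -1, axis=0) - p, axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        return cum / cum[-1]  # length n+1, last entry 1.0

    ta, tb = _params(pa), _params(pb)
    # monotone merge by normalized arc length: the strip cannot twist, so no
    # cross edge is ever created more than twice
    faces = []
    i = j = 0
    while i < na or j < nb:
        a_cur = loop_a[i % na]
        b_cur = loop_b[j % nb]
        adv_a = ta[i + 1] if i < na else np.inf
        adv_b = tb[j + 1] if j < nb else np.inf
        if adv_a <= adv_b:
            faces.append((a_cur, loop_a[(i + 1) % na], b_cur))
            i += 1
        else:
            faces.append((a_cur, loop_b[(j + 1) % nb], b_cur))
            j += 1
    f = np.asarray(faces, dtype=np.int64)
    keep = ~((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2]))
    return f[keep]


@dataclass
class DiscPartition:
    annulus_faces: np.ndarray
    nucleus_faces: np.ndarray
    nucleus_mesh: TriMesh
    annulus_mesh: TriMesh
    nucleus_solid: TetMesh
    annulus_solid: TetMesh
    z_threshold: float


def stitch_annulus_nucleus(
    disc: TriMesh,
    annulus_faces: np.ndarray,
    nucleus_faces: np.ndarray,
    frame: PCAFrame,
    tetrahedralize_parts: bool = True,
) -> DiscPartition:
    """Close nucleus and annulus into watertight solids sharing the interface.

    The wall between the two regions is triangulated directly on the original
    rim vertex loops of the nucleus face set (nearest-pair start, greedy
    minimal-edge advance), so both sub-surfaces close exactly and the interface
    node coordinates are bitwise identical across the two solids.
    """
    annulus_faces = np.asarray(annulus_faces, dtype=np.int64)
    nucleus_faces = np.asarray(nucleus_faces, dtype=np.int64)
    if len(nucleus_faces) == 0 or len(annulus_faces) == 0:
        raise MeshError("both annulus and nucleus face sets must be non-empty")
    sub = TriMesh(disc.vertices, disc.faces[nucleus_faces])
    loops = boundary_loops(sub)
    if len(loops) < 2:
        raise MeshError(f"expected 2 nucleus rim loops (top/bottom), found {len(loops)}")
    loops = sorted(loops, key=lambda l: -len(l))[:2]
    z0 = float(np.mean((disc.vertices[loops[0]] - frame.mean) @ frame.u3))
    z1 = float(np.mean((disc.vertices[loops[1]] - frame.mean) @ frame.u3))
    top_loop, bot_loop = (loops[0], loops[1]) if z0 > z1 else (loops[1], loops[0])
    wall = _zipper_loops(disc.vertices, top_loop, bot_loop)

    nucleus_mesh = orient_consistently(
        _compact(disc.vertices, np.concatenate([disc.faces[nucleus_faces], wall]))
    )
    annulus_mesh = orient_consistently(
        _compact(disc.vertices, np.concatenate([disc.faces[annulus_faces], wall[:, ::-1]]))
    )
    for name, m in (("nucleus", nucleus_mesh), ("annulus", annulus_mesh)):
        if not m.is_closed():
            m2, _ = fill_holes(m, max_perimeter=10.0 * _median_edge(disc))
            if not m2.is_closed():
                loops_left = boundary_loops(m2)
                raise MeshError(
                    f"{name} surface not watertight after hole filling: "
                    f"{len(loops_left)} open loops of sizes {[len(l) for l in loops_left]}"
                )
            if name == "nucleus":
                nucleus_mesh = m2
            else:
                annulus_mesh = m2
    _, _, thr = split_top_bottom(disc, nucleus_faces, frame)
    if tetrahedralize_parts:
        nucleus_solid = tetrahedralize(nucleus_mesh)
        annulus_solid = tetrahedralize(annulus_mesh)
    else:
        nucleus_solid = TetMesh(nucleus_mesh.vertices, np.zeros((0, 4), dtype=np.int64))
        annulus_solid = TetMesh(annulus_mesh.vertices, np.zeros((0, 4), dtype=np.int64))
    return DiscPartition(
        annulus_faces=annulus_faces,
        nucleus_faces=nucleus_faces,
        nucleus_mesh=nucleus_mesh,
        annulus_mesh=annulus_mesh,
        nucleus_solid=nucleus_solid,
        annulus_solid=annulus_solid,
        z_threshold=thr,
    )


def _median_edge(mesh: TriMesh) -> float:
    e = mesh.edges(unique=True)
    return float(np.median(np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)))


def split_disc(
    disc: TriMesh,
    scale: float = DEFAULT_NUCLEUS_SCALE,
    point_spacing: float = 1.0,
    n_samples: int = 64,
    superior=(0.0, 0.0, 1.0),
    anterior=(0.0, 1.0, 0.0),
    tetrahedralize_parts: bool = True,
) -> DiscPartition:
    """End-to-end nucleus/annulus separation of one disc surface."""
    frame = pca_frame(disc.vertices, superior=superior, anterior=anterior)
    curve = disc_boundary_curve(disc, frame, n_samples=n_samples)
    nucleus_curve = scale_curve(curve, scale)
    proto = build_nucleus_solid(nucleus_curve, disc, point_spacing=point_spacing, conform=False)
    proto = align_centroids(proto, disc)
    annulus_faces, nucleus_faces = partition_disc_faces(disc, proto)
    return stitch_annulus_nucleus(
        disc, annulus_faces, nucleus_faces, frame, tetrahedralize_parts=tetrahedralize_parts
    )
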