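"""Automatic ligament attachment and spring generation.

Attachment areas are selected by cutting planes through the vertebral center:
each plane's normal comes from a spherical-coordinate triple (phi, theta, r)
— N = r (sin phi cos theta, sin phi sin theta, cos phi), angles in degrees —
and the vertices with N . (P - O) > 0 form the attachment region.  A negative
r flips the selected side.  Two special modes exist: the posterior
longitudinal ligament uses the N posterior vertices closest to the vertebral
center, and the ligamentum flavum anchors around the midpoint between
adjacent vertebral centers.  Each ligament instance becomes 10 linear spring
elements between its two attachment regions.

The attachment table ships with the package defaults (phi, theta, r):
ALL lower (29.063, -85, 18), ALL upper (30, -85, -8), ITL left (35, 30, -1),
ITL right (35, 156, -1), CL lower left (25, 128.63, 16), CL lower right
(18, 61, 21), CL upper left (-4, 30, -28), CL upper right (-4, 140, -27),
SSL/ISL (25, 90.7, -30); PLL closest-N; LF midpoint.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .mesh_core import MeshError, TriMesh, centroid

DEFAULT_N_SPRINGS = 10
DEFAULT_PLL_CLOSEST_N = 20
DEFAULT_SPRING_AREA_MM2 = 10.0  # effective cross-section for k = E A / L


@dataclass
class SphericalCoordinate:
    """Polar angle from superior (+z), azimuth in the transverse plane, radius.

    Angles in degrees, radius in mm; a negative radius reverses the selected
    half-space side.
    """

    phi: float
    theta: float
    r: float


@dataclass
class AttachmentPlane:
    origin: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        if np.linalg.norm(self.normal) == 0:
            raise MeshError("attachment plane normal must be non-zero")


@dataclass
class LigamentSpec:
    """One row of the attachment table.

    ``mode`` is 'plane' (upper/lower spherical coords), 'closest_n' (PLL) or
    'midpoint' (LF).  For plane mode, ``coord_lower`` selects on the upper
    vertebra of a motion segment and ``coord_upper`` on the lower vertebra.
    """

    name: str
    mode: str = "plane"
    coord_lower: SphericalCoordinate | None = None
    coord_upper: SphericalCoordinate | None = None
    n_springs: int = DEFAULT_N_SPRINGS
    closest_n: int = DEFAULT_PLL_CLOSEST_N

    def __post_init__(self) -> None:
        if self.mode not in ("plane", "closest_n", "midpoint"):
            raise ValueError(f"unknown ligament mode {self.mode!r}")
        if self.mode == "plane" and (self.coord_lower is None or self.coord_upper is None):
            raise ValueError(f"plane-mode ligament {self.name} needs both coords")
        if self.n_springs < 1:
            raise ValueError("n_springs must be >= 1")


@dataclass
class SpringSet:
    """n_springs spring elements of one ligament instance."""

    ligament: str
    part_upper: str
    part_lower: str
    nodes_upper: np.ndarray  # vertex indices on the upper part's surface mesh
    nodes_lower: np.ndarray
    rest_lengths: np.ndarray

    @property
    def n_springs(self) -> int:
        return len(self.nodes_upper)


def spherical_to_cartesian(c: SphericalCoordinate) -> np.ndarray:
    """N = r (sin phi cos theta, sin phi sin theta, cos phi), degrees in."""
    phi = np.deg2rad(c.phi)
    theta = np.deg2rad(c.theta)
    return c.r * np.array(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def select_attachment_vertices(mesh: TriMesh, plane: AttachmentPlane) -> np.ndarray:
    """Indices of vertices strictly on the positive side: N . (P - O) > 0."""
    s = (mesh.vertices - plane.origin) @ plane.normal
    idx = np.flatnonzero(s > 0)
    if len(idx) == 0:
        warnings.warn("attachment plane selects no vertices", stacklevel=2)
    return idx


def attachment_region(mesh: TriMesh, center: np.ndarray, coord: SphericalCoordinate) -> np.ndarray:
    """Half-space vertex selection for one spherical-coordinate plane."""
    normal = spherical_to_cartesian(coord)
    return select_attachment_vertices(mesh, AttachmentPlane(origin=center, normal=normal))


def pll_attachment(
    mesh: TriMesh, center: np.ndarray, n: int, anterior=(0.0, 1.0, 0.0)
) -> np.ndarray:
    """The n posterior vertices nearest the vertebral center.

    Candidates are restricted to vertices posterior to the center (negative
    ``anterior`` coordinate); ties break by lower vertex index (stable sort).
    """
    if n < 1:
        raise MeshError("n must be >= 1")
    center = np.asarray(center, dtype=float)
    ant = np.asarray(anterior, dtype=float)
    ant = ant / np.linalg.norm(ant)
    post = np.flatnonzero((mesh.vertices - center) @ ant < 0)
    if len(post) == 0:
        raise MeshError("no posterior vertices available for PLL attachment")
    if len(post) < n:
        warnings.warn(
            f"only {len(post)} posterior candidates for PLL (requested {n})", stacklevel=2
        )
        return post
    d = np.linalg.norm(mesh.vertices[post] - center, axis=1)
    order = np.argsort(d, kind="stable")
    return post[order[:n]]


def lf_midpoints(center_upper: np.ndarray, center_lower: np.ndarray) -> np.ndarray:
    """Midpoint between adjacent vertebral centers (LF anchor locus)."""
    a = np.asarray(center_upper, dtype=float)
    b = np.asarray(center_lower, dtype=float)
    if np.allclose(a, b):
        raise MeshError("coincident vertebral centers")
    return 0.5 * (a + b)


def nearest_posterior_vertices(
    mesh: TriMesh, point: np.ndarray, center: np.ndarray, n: int, anterior=(0.0, 1.0, 0.0)
) -> np.ndarray:
    """The n posterior-of-center vertices nearest ``point`` (LF attachment)."""
    ant = np.asarray(anterior, dtype=float)
    ant = ant / np.linalg.norm(ant)
    post = np.flatnonzero((mesh.vertices - np.asarray(center)) @ ant < 0)
    if len(post) == 0:
        raise MeshError("no posterior vertices for LF attachment")
    d = np.linalg.norm(mesh.vertices[post] - np.asarray(point), axis=1)
    order = np.argsort(d, kind="stable")
    return post[order[: min(n, len(post))]]


def _farthest_point_sample(points: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    """Farthest-point subsample of idx, seeded at the centroid-nearest vertex."""
    pts = points[idx]
    c = pts.mean(axis=0)
    seed = int(np.argmin(np.linalg.norm(pts - c, axis=1)))
    chosen = [seed]
    d = np.linalg.norm(pts - pts[seed], axis=1)
    while len(chosen) < min(n, len(idx)):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(pts - pts[nxt], axis=1))
    out = idx[np.asarray(chosen)]
    if len(out) < n:  # tiny regions: cycle so exactly n anchors exist
        out = np.resize(out, n)
    return out


def build_ligament_springs(
    mesh_upper: TriMesh,
    region_upper: np.ndarray,
    mesh_lower: TriMesh,
    region_lower: np.ndarray,
    n_springs: int = DEFAULT_N_SPRINGS,
    ligament: str = "",
    part_upper: str = "",
    part_lower: str = "",
) -> SpringSet:
    """n_springs anchors on the upper region (farthest-point sampling) paired
    with their nearest vertices on the lower region; rest length = current
    distance."""
    region_upper = np.asarray(region_upper, dtype=np.int64)
    region_lower = np.asarray(region_lower, dtype=np.int64)
    if len(region_upper) == 0 or len(region_lower) == 0:
        raise MeshError(f"empty attachment region for ligament {ligament or '?'}")
    anchors = _farthest_point_sample(mesh_upper.vertices, region_upper, n_springs)
    lower_pts = mesh_lower.vertices[region_lower]
    up_pts = mesh_upper.vertices[anchors]
    d = np.linalg.norm(up_pts[:, None, :] - lower_pts[None, :, :], axis=2)
    j = np.argmin(d, axis=1)
    lower_nodes = region_lower[j]
    rest = d[np.arange(len(anchors)), j]
    if np.any(rest <= 0):
        raise MeshError(f"zero rest length in ligament {ligament or '?'}")
    return SpringSet(
        ligament=ligament,
        part_upper=part_upper,
        part_lower=part_lower,
        nodes_upper=anchors,
        nodes_lower=lower_nodes,
        rest_lengths=rest,
    )


def default_ligament_table() -> list[LigamentSpec]:
    """The package's built-in attachment table: 9 plane rows + PLL + LF."""
    C = SphericalCoordinate
    return [
        LigamentSpec("ALL", coord_lower=C(29.063, -85.0, 18.0), coord_upper=C(30.0, -85.0, -8.0)),
        LigamentSpec("ITL_left", coord_lower=C(35.0, 30.0, -1.0), coord_upper=C(35.0, 30.0, -1.0)),
        LigamentSpec("ITL_right", coord_lower=C(35.0, 156.0, -1.0), coord_upper=C(35.0, 156.0, -1.0)),
        LigamentSpec("CL_left", coord_lower=C(25.0, 128.63, 16.0), coord_upper=C(-4.0, 30.0, -28.0)),
        LigamentSpec("CL_right", coord_lower=C(18.0, 61.0, 21.0), coord_upper=C(-4.0, 140.0, -27.0)),
        LigamentSpec("SSL_ISL", coord_lower=C(25.0, 90.7, -30.0), coord_upper=C(25.0, 90.7, -30.0)),
        LigamentSpec("PLL", mode="closest_n"),
        LigamentSpec("LF", mode="midpoint"),
    ]


def table_coordinates() -> dict[str, tuple[float, float, float] | str]:
    """All 11 attachment-point rows keyed by point name.

    Nine rows carry (phi, theta, r); the PLL and LF rows use their special
    selection modes instead of a plane.
    """
    return {
        "ALL_lower": (29.063, -85.0, 18.0),
        "ALL_upper": (30.0, -85.0, -8.0),
        "ITL_left": (35.0, 30.0, -1.0),
        "ITL_right": (35.0, 156.0, -1.0),
        "CL_lower_left": (25.0, 128.63, 16.0),
        "CL_lower_right": (18.0, 61.0, 21.0),
        "CL_upper_left": (-4.0, 30.0, -28.0),
        "CL_upper_right": (-4.0, 140.0, -27.0),
        "SSL_ISL": (25.0, 90.7, -30.0),
        "PLL": "closest_n",
        "LF": "midpoint",
    }


def build_segment_springs(
    upper_name: str,
    upper_mesh: TriMesh,
    lower_name: str,
    lower_mesh: TriMesh,
    table: list[LigamentSpec] | None = None,
    anterior=(0.0, 1.0, 0.0),
) -> list[SpringSet]:
    """All ligament spring sets of one motion segment (adjacent vertebra pair).

    Plane-mode pairing: the 'lower' coordinates select on the upper vertebra
    and the 'upper' coordinates on the adjacent lower vertebra.
    """
    table = table if table is not None else default_ligament_table()
    c_up = centroid(upper_mesh.vertices)
    c_lo = centroid(lower_mesh.vertices)
    out: list[SpringSet] = []
    for spec in table:
        if spec.mode == "plane":
            reg_up = attachment_region(upper_mesh, c_up, spec.coord_lower)
            reg_lo = attachment_region(lower_mesh, c_lo, spec.coord_upper)
        elif spec.mode == "closest_n":
            reg_up = pll_attachment(upper_mesh, c_up, spec.closest_n, anterior=anterior)
            reg_lo = pll_attachment(lower_mesh, c_lo, spec.closest_n, anterior=anterior)
        else:  # midpoint (LF)
            mid = lf_midpoints(c_up, c_lo)
            reg_up = nearest_posterior_vertices(
                upper_mesh, mid, c_up, 2 * spec.n_springs, anterior=anterior
            )
            reg_lo = nearest_posterior_vertices(
                lower_mesh, mid, c_lo, 2 * spec.n_springs, anterior=anterior
            )
        out.append(
            build_ligament_springs(
                upper_mesh,
                reg_up,
                lower_mesh,
                reg_lo,
                n_springs=spec.n_springs,
                ligament=spec.name,
                part_upper=upper_name,
                part_lower=lower_name,
            )
        )
    return out


# ---------------------------------------------------------------------------
# table (de)serialisation
# ---------------------------------------------------------------------------


def save_ligament_table(table: list[LigamentSpec], path) -> None:
    rows = []
    for s in table:
        rows.append(
            {
                "name": s.name,
                "mode": s.mode,
                "phi_lower": s.coord_lower.phi if s.coord_lower else None,
                "theta_lower": s.coord_lower.theta if s.coord_lower else None,
                "r_lower": s.coord_lower.r if s.coord_lower else None,
                "phi_upper": s.coord_upper.phi if s.coord_upper else None,
                "theta_upper": s.coord_upper.theta if s.coord_upper else None,
                "r_upper": s.coord_upper.r if s.coord_upper else None,
                "n_springs": s.n_springs,
                "closest_n": s.closest_n,
            }
        )
    path = str(path)
    if path.endswith(".csv"):
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=list(rows[0]))
            w.writeheader()
            w.writerows(rows)
    else:
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=2)


def load_ligament_table(path) -> list[LigamentSpec]:
    path = str(path)
    if path.endswith(".csv"):
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    else:
        with open(path) as fh:
            rows = json.load(fh)
    out = []
    for r in rows:
        def _f(key):
            v = r.get(key)
            return None if v in (None, "", "None") else float(v)

        cl = (
            SphericalCoordinate(_f("phi_lower"), _f("theta_lower"), _f("r_lower"))
            if _f("phi_lower") is not None
            else None
        )
        cu = (
            SphericalCoordinate(_f("phi_upper"), _f("theta_upper"), _f("r_upper"))
            if _f("phi_upper") is not None
            else None
        )
        out.append(
            LigamentSpec(
                name=r["name"],
                mode=r.get("mode", "plane"),
                coord_lower=cl,
                coord_upper=cu,
                n_springs=int(r.get("n_springs", DEFAULT_N_SPRINGS)),
                closest_n=int(r.get("closest_n", DEFAULT_PLL_CLOSEST_N)),
            )
        )
    return out
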