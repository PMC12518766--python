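"""Vertebral endplate extraction by orientation filtering, thresholding,
clustering and radial shrinkage.

The "light direction" L is the vertebra's least-variance principal axis,
sign-fixed toward the declared superior direction.  Upper endplate: vertices
of upward faces above the mid height, single-linkage clustered at a distance
cutoff, largest cluster kept, then radially shrunk to the 70th percentile of
in-plane distances from the cluster centroid.  Lower endplate: candidates on
the far side of a plane 20 mm below the upper endplate plane on downward
faces, clustered the same way, shrunk to 55% of the maximum radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .mesh_core import MeshError, TriMesh, face_normals
from .disc_split import pca_frame

__all__ = [
    "EndplateParams",
    "EndplatePatch",
    "light_direction",
    "extract_upper_endplate",
    "extract_lower_endplate",
    "radial_percentile_filter",
    "radial_fraction_filter",
]


@dataclass
class EndplateParams:
    """Thresholds of the endplate recipe (defaults follow the reference values)."""

    cluster_dist: float = 1.5  # mm, single-linkage cutoff
    upper_keep_percentile: float = 70.0  # percent of radial distances kept
    lower_offset: float = 20.0  # mm below the upper endplate plane
    lower_keep_fraction: float = 0.55  # of the max radial distance

    def __post_init__(self) -> None:
        if self.cluster_dist <= 0 or self.lower_offset <= 0:
            raise ValueError("cluster_dist and lower_offset must be positive")
        if not (0 < self.upper_keep_percentile <= 100):
            raise ValueError("upper_keep_percentile must be in (0, 100]")
        if not (0 < self.lower_keep_fraction <= 1):
            raise ValueError("lower_keep_fraction must be in (0, 1]")


@dataclass
class EndplatePatch:
    """Vertex subset of a vertebra forming one endplate, with its fitted plane."""

    vertex_indices: np.ndarray  # into the parent vertebra mesh
    faces: np.ndarray  # triangles (parent indices) fully inside the vertex set
    plane_point: np.ndarray
    plane_normal: np.ndarray  # unit; along L for upper, against L for lower
    centroid: np.ndarray

    def patch_mesh(self, parent: TriMesh) -> TriMesh:
        from .mesh_core import _compact

        return _compact(parent.vertices, self.faces)


def light_direction(vertebra: TriMesh, superior=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Least-variance principal axis of the vertex cloud, toward ``superior``."""
    if vertebra.n_vertices < 4:
        raise MeshError("light_direction requires at least 4 vertices")
    frame = pca_frame(vertebra.vertices, superior=superior)
    return frame.u3


def _cluster_labels(points: np.ndarray, cutoff: float) -> np.ndarray:
    """Single-linkage clustering at a Euclidean cutoff (radius-graph components)."""
    tree = cKDTree(points)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    n = len(points)
    if len(pairs) == 0:
        return np.arange(n)
    adj = coo_matrix(
        (
            np.ones(2 * len(pairs)),
            (
                np.concatenate([pairs[:, 0], pairs[:, 1]]),
                np.concatenate([pairs[:, 1], pairs[:, 0]]),
            ),
        ),
        shape=(n, n),
    )
    _, labels = connected_components(adj, directed=False)
    return labels


def _largest_cluster(points: np.ndarray, idx: np.ndarray, cutoff: float, z: np.ndarray) -> np.ndarray:
    """Indices (subset of idx) of the largest cluster; ties -> larger mean z."""
    labels = _cluster_labels(points, cutoff)
    best = None
    for lab in np.unique(labels):
        sel = labels == lab
        key = (int(sel.sum()), float(z[sel].mean()))
        if best is None or key > best[0]:
            best = (key, sel)
    return idx[best[1]]


def radial_percentile_filter(
    points: np.ndarray, L: np.ndarray, percentile: float
) -> np.ndarray:
    """Boolean keep-mask: in-plane radius <= linear-interpolated percentile.

    Radii are measured from the point centroid in the plane orthogonal to L.
    """
    r = _planar_radii(points, L)
    thr = float(np.percentile(r, percentile))  # numpy 'linear' interpolation
    return r <= thr


def radial_fraction_filter(points: np.ndarray, L: np.ndarray, fraction: float) -> np.ndarray:
    """Boolean keep-mask: in-plane radius <= fraction * max radius."""
    r = _planar_radii(points, L)
    return r <= fraction * float(r.max())


def _planar_radii(points: np.ndarray, L: np.ndarray) -> np.ndarray:
    c = points.mean(axis=0)
    d = points - c
    d = d - np.outer(d @ L, L)
    return np.linalg.norm(d, axis=1)


def _fit_plane(points: np.ndarray, orient: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane (point, unit normal oriented along ``orient``)."""
    c = points.mean(axis=0)
    q = points - c
    _, _, vt = np.linalg.svd(q, full_matrices=False)
    n = vt[-1]
    if n @ orient < 0:
        n = -n
    return c, n


def _patch_faces(mesh: TriMesh, kept: np.ndarray) -> np.ndarray:
    mask = np.zeros(mesh.n_vertices, dtype=bool)
    mask[kept] = True
    return mesh.faces[mask[mesh.faces].all(axis=1)]


def extract_upper_endplate(
    vertebra: TriMesh, params: EndplateParams | None = None, superior=(0.0, 0.0, 1.0)
) -> EndplatePatch:
    """Upper endplate patch: upward faces, upper half, largest cluster, shrink."""
    params = params or EndplateParams()
    L = light_direction(vertebra, superior=superior)
    fn = face_normals(vertebra)
    up_faces = fn @ L > 0
    cand = np.unique(vertebra.faces[up_faces])
    if len(cand) == 0:
        raise MeshError("no upward-facing vertices found")
    z = vertebra.vertices @ L
    z_thr = 0.5 * (float(z.max()) + float(z.min()))
    cand = cand[z[cand] > z_thr]
    if len(cand) == 0:
        raise MeshError("empty upper-endplate candidate set above the mid height")
    cand = _largest_cluster(vertebra.vertices[cand], cand, params.cluster_dist, z[cand])
    keep = radial_percentile_filter(
        vertebra.vertices[cand], L, params.upper_keep_percentile
    )
    kept = cand[keep]
    if len(kept) == 0:
        raise MeshError("upper endplate empty after radial shrinkage")
    pts = vertebra.vertices[kept]
    p0, n = _fit_plane(pts, L)
    return EndplatePatch(
        vertex_indices=kept,
        faces=_patch_faces(vertebra, kept),
        plane_point=p0,
        plane_normal=n,
        centroid=pts.mean(axis=0),
    )


def extract_lower_endplate(
    vertebra: TriMesh,
    upper: EndplatePatch,
    params: EndplateParams | None = None,
    superior=(0.0, 0.0, 1.0),
) -> EndplatePatch:
    """Lower endplate patch via the parallel plane ``lower_offset`` below the upper.

    Candidates must lie on the far side of that plane *and* on downward faces
    (the plane-side rule alone would admit lateral-wall vertices on tall
    vertebrae); the largest cluster is then shrunk to
    ``lower_keep_fraction`` of its maximum in-plane radius.
    """
    params = params or EndplateParams()
    L = light_direction(vertebra, superior=superior)
    plane_point = upper.plane_point - params.lower_offset * L
    side = (vertebra.vertices - plane_point) @ upper.plane_normal < 0
    fn = face_normals(vertebra)
    down = fn @ L < 0
    cand = np.unique(vertebra.faces[down])
    cand = cand[side[cand]]
    if len(cand) == 0:
        raise MeshError(
            f"no lower-endplate candidates {params.lower_offset} mm below the upper "
            "plane; the vertebra may be shorter than lower_offset"
        )
    z = vertebra.vertices @ L
    cand = _largest_cluster(vertebra.vertices[cand], cand, params.cluster_dist, -z[cand])
    keep = radial_fraction_filter(vertebra.vertices[cand], L, params.lower_keep_fraction)
    kept = cand[keep]
    if len(kept) == 0:
        raise MeshError("lower endplate empty after radial shrinkage")
    pts = vertebra.vertices[kept]
    p0, n = _fit_plane(pts, -L)
    return EndplatePatch(
        vertex_indices=kept,
        faces=_patch_faces(vertebra, kept),
        plane_point=p0,
        plane_normal=n,
        centroid=pts.mean(axis=0),
    )
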