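"""Cartilage volumes filling the vertebra-disc gaps.

Each vertebra-disc interface gets one cartilage segment: the vertebral
endplate patch on one side, the disc faces that look back at it within a gap
threshold on the other, and a lofted side wall closing the ring between their
boundary loops.  Labels follow the L<k>D<j> convention, e.g. L1D1 is the
cartilage between vertebra L1 and disc D1 (the L1/L2 disc), L2D1 between L2
and the same disc.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .endplates import EndplatePatch
from .mesh_core import (
    MeshError,
    TetMesh,
    TriMesh,
    _compact,
    boundary_loops,
    distance_to_mesh,
    face_normals,
    fill_holes,
    orient_consistently,
    tetrahedralize,
)
from .disc_split import _zipper_loops

DEFAULT_MAX_GAP = 2.0  # mm; above segmentation gaps, below disc height


@dataclass
class CartilageSegment:
    label: str  # e.g. "L1D1"
    surface: TriMesh
    solid: TetMesh

    @property
    def volume(self) -> float:
        return self.solid.volume()


def contact_faces(
    disc_part: TriMesh,
    endplate: EndplatePatch,
    parent: TriMesh,
    max_gap: float = DEFAULT_MAX_GAP,
) -> np.ndarray:
    """Disc-part faces whose centroid is within ``max_gap`` of the endplate
    patch and which face back toward it.

    ``parent`` is the vertebra mesh the endplate indexes into.  Returns face
    indices into ``disc_part``; may be empty (warned).
    """
    if max_gap <= 0:
        raise MeshError("max_gap must be positive")
    patch = endplate.patch_mesh(parent)
    if patch.n_faces == 0:
        return np.zeros(0, dtype=np.int64)
    cent = disc_part.face_centroids()
    d = distance_to_mesh(patch, cent)
    # endplate-facing: the disc face's outward normal opposes the endplate
    # plane normal (which points from the vertebra toward the disc); the
    # 0.3 cosine margin excludes tangential wall faces grazing the gap
    fn = face_normals(disc_part)
    facing = fn @ endplate.plane_normal < -0.3
    sel = np.flatnonzero((d <= max_gap) & facing)
    if len(sel) == 0:
        warnings.warn("no disc faces within max_gap of the endplate", stacklevel=2)
    return sel


def build_cartilage(
    endplate: EndplatePatch,
    parent: TriMesh,
    disc_part: TriMesh,
    nucleus_contact: np.ndarray,
    annulus_part: TriMesh | None = None,
    annulus_contact: np.ndarray | None = None,
    label: str = "",
    tetrahedralize_part: bool = True,
) -> CartilageSegment:
    """Join the endplate patch and the disc contact faces into a closed solid.

    The union of the contact face sets and the endplate patch are stitched by
    a greedy loft between their outer boundary loops; remaining small loops
    are hole-filled, the surface is oriented outward and tetrahedralized.
    """
    pieces = []
    if len(nucleus_contact):
        pieces.append((disc_part, np.asarray(nucleus_contact, dtype=np.int64)))
    if annulus_part is not None and annulus_contact is not None and len(annulus_contact):
        pieces.append((annulus_part, np.asarray(annulus_contact, dtype=np.int64)))
    if not pieces:
        raise MeshError(f"cartilage {label or '?'}: both contact face sets are empty")
    patch = endplate.patch_mesh(parent)
    if patch.n_faces == 0:
        raise MeshError(f"cartilage {label or '?'}: empty endplate patch")
    # assemble one vertex buffer: patch block + one block per contact piece
    verts = [patch.vertices]
    faces = [patch.faces]
    off = patch.n_vertices
    for mesh, sel in pieces:
        sub = _compact(mesh.vertices, mesh.faces[sel])
        verts.append(sub.vertices)
        faces.append(sub.faces + off)
        off += sub.n_vertices
    V = np.concatenate(verts)
    F = np.concatenate(faces)
    # weld bitwise-coincident vertices (nucleus/annulus blocks share the disc
    # rim coordinates) so interior seams close instead of leaving open loops
    q = np.round(V / 1e-9).astype(np.int64)
    _, first, inv = np.unique(q, axis=0, return_index=True, return_inverse=True)
    V = V[first]
    F = inv[F]
    F = F[~((F[:, 0] == F[:, 1]) | (F[:, 1] == F[:, 2]) | (F[:, 0] == F[:, 2]))]
    key = np.sort(F, axis=1)
    _, uniq_first = np.unique(key, axis=0, return_index=True)
    F = F[np.sort(uniq_first)]  # coincident duplicates (shared interface copies)
    F = _drop_small_islands(V, F)
    F = _open_boundary_pinches(V, F)
    combined = TriMesh(V, F)
    loops = boundary_loops(combined)
    if len(loops) >= 2:
        # wall between the two longest loops (endplate rim vs contact rim)
        loops = sorted(loops, key=lambda l: -_loop_perimeter(V, l))
        wall = _zipper_loops(V, loops[0], loops[1])
        combined = TriMesh(V, np.concatenate([F, wall]))
    closed, _ = fill_holes(combined, max_perimeter=np.inf)
    closed = orient_consistently(closed.clean(), outward=True)
    if not closed.is_closed():
        raise MeshError(f"cartilage {label or '?'}: surface not watertight after stitching")
    solid = (
        tetrahedralize(closed)
        if tetrahedralize_part
        else TetMesh(closed.vertices, np.zeros((0, 4), dtype=np.int64))
    )
    return CartilageSegment(label=label, surface=closed, solid=solid)


def _drop_small_islands(V: np.ndarray, F: np.ndarray, min_frac: float = 0.02) -> np.ndarray:
    """Remove tiny detached face islands (contact-set speckle) before lofting."""
    from spineforge.mesh_core import face_components

    m = TriMesh(V, F)
    labels = face_components(m)
    keep = np.zeros(len(F), dtype=bool)
    thr = max(8, int(min_frac * len(F)))
    for lab in np.unique(labels):
        sel = labels == lab
        if sel.sum() >= thr:
            keep |= sel
    return F[keep] if keep.any() else F


def _open_boundary_pinches(V: np.ndarray, F: np.ndarray, max_iter: int = 50) -> np.ndarray:
    """Delete one face at each boundary pinch vertex until none remain.

    A pinch vertex carries four or more boundary edges (two loops kissing);
    removing an incident boundary face opens the pinch so the loops become a
    single clean walk, which the lofting step requires.
    """
    F = F.copy()
    for _ in range(max_iter):
        m = TriMesh(V, F)
        uniq, counts = m.edge_face_incidence()
        be = uniq[counts == 1]
        if len(be) == 0:
            return F
        deg = np.bincount(be.ravel(), minlength=len(V))
        pinched = np.flatnonzero(deg >= 3)
        if len(pinched) == 0:
            return F
        areas = m.face_areas()
        drop = set()
        for pv in pinched:
            inc = np.flatnonzero((F == pv).any(axis=1))
            if len(inc):
                drop.add(int(inc[np.argmin(areas[inc])]))
        if not drop:
            return F
        F = F[[i for i in range(len(F)) if i not in drop]]
    return F


def _loop_perimeter(vertices: np.ndarray, loop: np.ndarray) -> float:
    p = vertices[loop]
    return float(np.linalg.norm(np.roll(p, -1, axis=0) - p, axis=1).sum())


def interface_labels(n_levels: int) -> list[tuple[str, str, str, str]]:
    """(label, vertebra, endplate side, disc) for every vertebra-disc interface.

    For an n-level stack: L<k>D<k> uses the lower endplate of L<k> against
    disc D<k>; L<k+1>D<k> uses the upper endplate of L<k+1> against the same
    disc.  n=5 yields the 8 segments L1D1, L2D1, L2D2, ..., L5D4.
    """
    out = []
    for k in range(1, n_levels):
        out.append((f"L{k}D{k}", f"L{k}", "lower", f"D{k}"))
        out.append((f"L{k + 1}D{k}", f"L{k + 1}", "upper", f"D{k}"))
    return sorted(out, key=lambda t: (int(t[1][1:]), int(t[3][1:])))
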