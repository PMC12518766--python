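"""Shared fixtures: analytic primitives and one full synthetic pipeline run.

The expensive end-to-end pipeline runs once per session and backs every
structural-inventory and conservation test.
"""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from spineforge.mesh_core import TriMesh
from spineforge.pipeline import PipelineResult, run_pipeline
from spineforge.synthetic_spine import SpineFixtureParams, make_lumbar_stack


def icosphere(radius: float = 10.0, subdivisions: int = 3) -> TriMesh:
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriMesh(np.asarray(m.vertices), np.asarray(m.faces))


def unit_cube() -> TriMesh:
    m = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return TriMesh(np.asarray(m.vertices), np.asarray(m.faces))


def cube_fan() -> TriMesh:
    """Unit cube with each square face split into a 4-triangle fan.

    Symmetric triangulation: every corner touches two equal-area triangles per
    incident face, so area-weighted corner normals are the space diagonals.
    """
    m = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    V = list(np.asarray(m.vertices, dtype=float))
    F = []
    quads = {}
    # regroup the 12 box triangles into their 6 quads by shared normal+offset
    fn = np.asarray(m.face_normals).round(6)
    for fi, tri in enumerate(np.asarray(m.faces)):
        key = tuple(fn[fi]) + (round(float(np.dot(fn[fi], m.vertices[tri[0]])), 6),)
        quads.setdefault(key, set()).update(int(v) for v in tri)
    for key, vids in quads.items():
        vids = sorted(vids)
        center = np.mean([V[i] for i in vids], axis=0)
        cid = len(V)
        V.append(center)
        n = np.asarray(key[:3])
        # order the 4 corners counter-clockwise around the face normal
        ref = V[vids[0]] - center
        ref = ref / np.linalg.norm(ref)
        t2 = np.cross(n, ref)
        ang = sorted(
            vids,
            key=lambda i: np.arctan2(np.dot(V[i] - center, t2), np.dot(V[i] - center, ref)),
        )
        for k in range(4):
            a, b = ang[k], ang[(k + 1) % 4]
            F.append((a, b, cid))
    return TriMesh(np.asarray(V), np.asarray(F, dtype=np.int64))


def flat_grid(n: int = 5) -> TriMesh:
    """Flat z=0 grid with uniform diagonals: interior vertices are Laplacian
    fixed points (each sits at its 1-ring centroid)."""
    xs, ys = np.meshgrid(np.arange(float(n)), np.arange(float(n)), indexing="ij")
    V = np.stack([xs.ravel(), ys.ravel(), np.zeros(n * n)], axis=1)
    F = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            b = i * n + j + 1
            c = (i + 1) * n + j
            d = (i + 1) * n + j + 1
            F += [(a, d, b), (a, c, d)]
    return TriMesh(V, np.asarray(F, dtype=np.int64))


def small_params(seed: int = 11) -> SpineFixtureParams:
    """Low-resolution stack parameters for fast per-stage tests."""
    return SpineFixtureParams(seed=seed, subdivisions=3, disc_resolution=(24, 9))


@pytest.fixture(scope="session")
def default_stack() -> dict[str, TriMesh]:
    return make_lumbar_stack(SpineFixtureParams(seed=1))


@pytest.fixture(scope="session")
def pipeline_result(default_stack) -> PipelineResult:
    return run_pipeline(default_stack)


def random_rotation(seed: int) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=seed).as_matrix()
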