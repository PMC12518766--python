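"""Surface-mesh file I/O: STL (binary/ASCII), OBJ (read), legacy ASCII VTK.

STL carries no connectivity, so vertices are de-duplicated on read with a
1e-6 mm tolerance.  VTK files are written in the legacy ASCII format so every
artifact in the pipeline stays plain text.
"""

from __future__ import annotations

import numpy as np

from .mesh_core import MeshError, TetMesh, TriMesh

STL_WELD_TOL = 1e-6  # mm


def _weld(vertices: np.ndarray, faces: np.ndarray, tol: float = STL_WELD_TOL) -> TriMesh:
    q = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(q, axis=0, return_index=True, return_inverse=True)
    f = inverse[faces]
    keep = ~(
        (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
    )
    return TriMesh(vertices[first], f[keep]).clean()


def load_mesh(path) -> TriMesh:
    """Read an STL (binary or ASCII, auto-detected) or OBJ surface."""
    import trimesh as _tm

    m = _tm.load(str(path), force="mesh", process=False)
    v = np.asarray(m.vertices, dtype=float)
    f = np.asarray(m.faces, dtype=np.int64)
    if str(path).lower().endswith(".stl"):
        return _weld(v, f)
    return TriMesh(v, f).clean()


def save_stl(mesh: TriMesh, path) -> None:
    """Write binary STL."""
    mesh.to_trimesh().export(str(path))


def save_vtk_polydata(mesh: TriMesh, path) -> None:
    """Legacy ASCII VTK PolyData surface."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nspineforge surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for p in mesh.vertices:
            fh.write(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
        fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def load_vtk_polydata(path) -> TriMesh:
    with open(path) as fh:
        tokens = fh.read().split()
    return _parse_vtk_surface(tokens)


def _parse_vtk_surface(tokens: list[str]) -> TriMesh:
    it = iter(range(len(tokens)))
    i = 0
    pts = None
    faces = []
    while i < len(tokens):
        t = tokens[i].upper()
        if t == "POINTS":
            n = int(tokens[i + 1])
            vals = [float(x) for x in tokens[i + 3 : i + 3 + 3 * n]]
            pts = np.asarray(vals).reshape(n, 3)
            i += 3 + 3 * n
        elif t == "POLYGONS":
            m = int(tokens[i + 1])
            total = int(tokens[i + 2])
            j = i + 3
            for _ in range(m):
                k = int(tokens[j])
                if k != 3:
                    raise MeshError("only triangle polygons supported")
                faces.append([int(tokens[j + 1]), int(tokens[j + 2]), int(tokens[j + 3])])
                j += k + 1
            i = i + 3 + total
        else:
            i += 1
    if pts is None:
        raise MeshError("no POINTS section in VTK file")
    return TriMesh(pts, np.asarray(faces, dtype=np.int64))


def save_vtk_unstructured(tet: TetMesh, path, part_label: int | None = None) -> None:
    """Legacy ASCII VTK unstructured grid of tet4 cells.

    When ``part_label`` is given it is written as a per-cell integer field.
    """
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nspineforge tet mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {tet.n_vertices} double\n")
        for p in tet.vertices:
            fh.write(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
        fh.write(f"CELLS {tet.n_cells} {5 * tet.n_cells}\n")
        for c in tet.cells:
            fh.write(f"4 {c[0]} {c[1]} {c[2]} {c[3]}\n")
        fh.write(f"CELL_TYPES {tet.n_cells}\n")
        fh.write("\n".join(["10"] * tet.n_cells) + "\n")
        if part_label is not None:
            fh.write(f"CELL_DATA {tet.n_cells}\n")
            fh.write("SCALARS part_label int 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join([str(part_label)] * tet.n_cells) + "\n")


def load_vtk_unstructured(path) -> TetMesh:
    with open(path) as fh:
        tokens = fh.read().split()
    i = 0
    pts = None
    cells = []
    while i < len(tokens):
        t = tokens[i].upper()
        if t == "POINTS":
            n = int(tokens[i + 1])
            vals = [float(x) for x in tokens[i + 3 : i + 3 + 3 * n]]
            pts = np.asarray(vals).reshape(n, 3)
            i += 3 + 3 * n
        elif t == "CELLS":
            m = int(tokens[i + 1])
            total = int(tokens[i + 2])
            j = i + 3
            for _ in range(m):
                k = int(tokens[j])
                if k != 4:
                    raise MeshError("only tet4 cells supported")
                cells.append([int(tokens[j + q]) for q in range(1, 5)])
                j += k + 1
            i = i + 3 + total
        else:
            i += 1
    if pts is None:
        raise MeshError("no POINTS section in VTK file")
    return TetMesh(pts, np.asarray(cells, dtype=np.int64))


def save_vtk_polylines(points: np.ndarray, lines: np.ndarray, path) -> None:
    """Legacy ASCII VTK PolyData with LINES cells (spring visualisation)."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    lines = np.asarray(lines, dtype=np.int64).reshape(-1, 2)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nspineforge springs\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(points)} double\n")
        for p in points:
            fh.write(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
        fh.write(f"LINES {len(lines)} {3 * len(lines)}\n")
        for a, b in lines:
            fh.write(f"2 {a} {b}\n")
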