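"""FE model assembly and export (FEBio-format XML and legacy VTK).

Assembles bone, disc, cartilage and ligament results into a single model
carrying the standard lumbar material cards, the four physiological load
cases, auto-generated contact definitions (stick nucleus-annulus, tied
cartilage-endplate, node-to-surface ligament attachments), the rigid
constraint on L5's lower endplate and the rigid loading body on L1's upper
endplate.

Material defaults: cortical bone E=12000 MPa / nu=0.3; cancellous E=100 /
nu=0.2; nucleus Mooney-Rivlin c1=0.12, c2=0.09, bulk 666.67 MPa; annulus
c1=0.56, c2=0.14, bulk 14.89 MPa (density 1.0003 g/cm^3 for both); cartilage
E=23.8 / nu=0.4; ligaments linear springs with E=0.22 MPa; the two boundary
endplates rigid.  Load cases: extension Mx=-7.5 Nm / Fz=-50 N; flexion
Mx=7.5 / Fz=-117.5; axial rotation Mz=5.5 / Fz=-72; lateral bending My=7.8 /
Fz=-70.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lxml import etree
from scipy.spatial import cKDTree

from .ligaments import DEFAULT_SPRING_AREA_MM2, SpringSet
from .mesh_core import MeshError, TetMesh

NODE_TOLERANCE = 0.01  # mm, coincident-node report tolerance
DEFAULT_LOAD_STEPS = 10  # quasi-static increments


@dataclass
class MaterialCard:
    name: str
    model: str  # isotropic_elastic | mooney_rivlin | rigid | linear_spring
    E: float | None = None
    nu: float | None = None
    c1: float | None = None
    c2: float | None = None
    bulk: float | None = None
    density: float | None = None

    def __post_init__(self) -> None:
        if self.model == "isotropic_elastic":
            if not (self.E and self.E > 0) or not (-1 < self.nu < 0.5):
                raise ValueError(f"invalid elastic card {self.name}")
        elif self.model == "mooney_rivlin":
            if not (self.bulk and self.bulk > 0):
                raise ValueError(f"invalid Mooney-Rivlin card {self.name}")
        elif self.model == "linear_spring":
            if not (self.E and self.E > 0):
                raise ValueError(f"invalid spring card {self.name}")
        elif self.model != "rigid":
            raise ValueError(f"unknown material model {self.model}")


@dataclass
class LoadCase:
    name: str
    Fx: float = 0.0
    Fy: float = 0.0
    Fz: float = 0.0
    Mx: float = 0.0
    My: float = 0.0
    Mz: float = 0.0
    application: str = "L1_upper_endplate"


@dataclass
class ContactDefinition:
    kind: str  # stick | tied | node_to_surface
    primary: str
    secondary: str
    tolerance: float = NODE_TOLERANCE

    def __post_init__(self) -> None:
        if self.kind not in ("stick", "tied", "node_to_surface"):
            raise ValueError(f"unknown contact kind {self.kind}")
        if self.tolerance <= 0:
            raise ValueError("contact tolerance must be positive")


@dataclass
class FEModel:
    parts: dict[str, TetMesh] = field(default_factory=dict)
    materials: dict[str, str] = field(default_factory=dict)  # part -> material name
    material_cards: dict[str, MaterialCard] = field(default_factory=dict)
    springs: list[SpringSet] = field(default_factory=list)
    spring_coords: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    contacts: list[ContactDefinition] = field(default_factory=list)
    fixed_nodes: dict[str, np.ndarray] = field(default_factory=dict)  # part -> node ids
    rigid_node_sets: dict[str, tuple[str, np.ndarray]] = field(default_factory=dict)
    loads: list[LoadCase] = field(default_factory=list)
    spring_area: float = DEFAULT_SPRING_AREA_MM2

    def validate(self) -> None:
        for part in self.parts:
            if part not in self.materials:
                raise MeshError(f"part {part} has no material assigned")
            if self.materials[part] not in self.material_cards:
                raise MeshError(f"part {part} references unknown material {self.materials[part]}")
        for part, nodes in self.fixed_nodes.items():
            if part not in self.parts:
                raise MeshError(f"fixed BC references unknown part {part}")
            if len(nodes) == 0:
                raise MeshError(f"empty fixed node set on {part}")
            if nodes.max() >= self.parts[part].n_vertices:
                raise MeshError(f"fixed node id out of range on {part}")

    def total_springs(self) -> int:
        return sum(s.n_springs for s in self.springs)


def default_materials() -> dict[str, MaterialCard]:
    """The standard lumbar material cards (MPa, g/cm^3)."""
    cards = [
        MaterialCard("cortical", "isotropic_elastic", E=12000.0, nu=0.3),
        MaterialCard("cancellous", "isotropic_elastic", E=100.0, nu=0.2),
        MaterialCard("nucleus", "mooney_rivlin", c1=0.12, c2=0.09, bulk=666.67, density=1.0003),
        MaterialCard("annulus", "mooney_rivlin", c1=0.56, c2=0.14, bulk=14.89, density=1.0003),
        MaterialCard("cartilage", "isotropic_elastic", E=23.8, nu=0.4, density=1.0003),
        MaterialCard("ligament", "linear_spring", E=0.22),
        MaterialCard("rigid_endplate_L1_upper", "rigid"),
        MaterialCard("rigid_endplate_L5_lower", "rigid"),
    ]
    return {c.name: c for c in cards}


def default_load_cases() -> list[LoadCase]:
    """Extension, flexion, axial rotation and lateral bending (N, N m)."""
    return [
        LoadCase("extension", Mx=-7.5, Fz=-50.0),
        LoadCase("flexion", Mx=7.5, Fz=-117.5),
        LoadCase("axial_rotation", Mz=5.5, Fz=-72.0),
        LoadCase("lateral_bending", My=7.8, Fz=-70.0),
    ]


def _surface_node_ids(part: TetMesh, points: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Node ids of ``part`` coincident (within tol) with the given points."""
    tree = cKDTree(part.vertices)
    d, idx = tree.query(points)
    return np.unique(idx[d <= tol])


def assemble_model(
    bones: dict[str, "object"],
    discs: dict[str, "object"],
    cartilage: list["object"],
    springs: list[SpringSet],
    spring_coords: list[tuple[np.ndarray, np.ndarray]],
    endplates: dict[str, dict[str, "object"]],
    vertebra_surfaces: dict[str, "object"],
    materials: dict[str, MaterialCard] | None = None,
    loads: list[LoadCase] | None = None,
) -> FEModel:
    """Assemble all pipeline outputs into a validated FE model.

    ``bones`` maps L-level -> BoneSplitResult, ``discs`` maps D-level ->
    DiscPartition, ``cartilage`` is a list of CartilageSegment, ``endplates``
    maps L-level -> {"upper": patch, "lower": patch}, ``vertebra_surfaces``
    maps L-level -> TriMesh.
    """
    materials = materials or default_materials()
    loads = loads if loads is not None else default_load_cases()
    model = FEModel(material_cards=materials, loads=loads)
    for lev, res in bones.items():
        model.parts[f"{lev}_cortical"] = res.cortical_shell
        model.parts[f"{lev}_cancellous"] = res.cancellous_core
        model.materials[f"{lev}_cortical"] = "cortical"
        model.materials[f"{lev}_cancellous"] = "cancellous"
    for lev, part in discs.items():
        model.parts[f"{lev}_nucleus"] = part.nucleus_solid
        model.parts[f"{lev}_annulus"] = part.annulus_solid
        model.materials[f"{lev}_nucleus"] = "nucleus"
        model.materials[f"{lev}_annulus"] = "annulus"
        model.contacts.append(
            ContactDefinition("stick", f"{lev}_nucleus", f"{lev}_annulus")
        )
    for seg in cartilage:
        name = f"cartilage_{seg.label}"
        model.parts[name] = seg.solid
        model.materials[name] = "cartilage"
        lev = seg.label.split("D")[0]  # e.g. "L1D1" -> "L1"
        model.contacts.append(ContactDefinition("tied", name, f"{lev}_cortical"))
    model.springs = list(springs)
    model.spring_coords = list(spring_coords)
    for s in springs:
        model.contacts.append(
            ContactDefinition(
                "node_to_surface", f"ligament_{s.ligament}_{s.part_upper}", f"{s.part_lower}_cortical"
            )
        )
    levels = sorted(bones, key=lambda s: int(s[1:]))
    lowest, highest = levels[-1], levels[0]
    # fixed BC: all cortical nodes on the lower endplate of the lowest level
    lo_patch = endplates[lowest]["lower"]
    lo_pts = vertebra_surfaces[lowest].vertices[lo_patch.vertex_indices]
    fixed = _surface_node_ids(model.parts[f"{lowest}_cortical"], lo_pts)
    if len(fixed) == 0:
        raise MeshError(f"no {lowest} cortical nodes matched the lower endplate patch")
    model.fixed_nodes[f"{lowest}_cortical"] = fixed
    # rigid loading body: upper endplate of the highest level
    up_patch = endplates[highest]["upper"]
    up_pts = vertebra_surfaces[highest].vertices[up_patch.vertex_indices]
    rigid = _surface_node_ids(model.parts[f"{highest}_cortical"], up_pts)
    model.rigid_node_sets[f"{highest}_upper_endplate"] = (
        f"rigid_endplate_{highest}_upper",
        rigid,
    )
    model.rigid_node_sets[f"{lowest}_lower_endplate"] = (
        f"rigid_endplate_{lowest}_lower",
        fixed,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# FEBio export
# ---------------------------------------------------------------------------

_FEB_MAT_TYPE = {
    "isotropic_elastic": "isotropic elastic",
    "mooney_rivlin": "Mooney-Rivlin",
    "rigid": "rigid body",
}
_FEB_CONTACT_TYPE = {
    "stick": "sticky",
    "tied": "tied",
    "node_to_surface": "sliding-node-on-facet",
}


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def export_feb(model: FEModel, path, n_steps: int = DEFAULT_LOAD_STEPS) -> None:
    """Write the model as FEBio-format XML (spec 2.5).

    One quasi-static <Step> per load case, each ramping its rigid-body force
    and moment over ``n_steps`` equal increments.  Node coordinates carry 9
    significant digits.
    """
    model.validate()
    root = etree.Element("febio_spec", version="2.5")
    etree.SubElement(root, "Module", type="solid")
    glob = etree.SubElement(root, "Globals")
    const = etree.SubElement(glob, "Constants")
    etree.SubElement(const, "T").text = "0"
    etree.SubElement(const, "R").text = "0"
    etree.SubElement(const, "Fc").text = "0"

    mat = etree.SubElement(root, "Material")
    mat_ids: dict[str, int] = {}
    for i, (name, card) in enumerate(model.material_cards.items(), start=1):
        mat_ids[name] = i
        if card.model == "linear_spring":
            continue  # springs are discrete materials, not solid materials
        m = etree.SubElement(
            mat, "material", id=str(i), name=name, type=_FEB_MAT_TYPE[card.model]
        )
        if card.model == "isotropic_elastic":
            etree.SubElement(m, "E").text = _fmt(card.E)
            etree.SubElement(m, "v").text = _fmt(card.nu)
            if card.density:
                etree.SubElement(m, "density").text = _fmt(card.density)
        elif card.model == "mooney_rivlin":
            etree.SubElement(m, "c1").text = _fmt(card.c1)
            etree.SubElement(m, "c2").text = _fmt(card.c2)
            etree.SubElement(m, "k").text = _fmt(card.bulk)
            if card.density:
                etree.SubElement(m, "density").text = _fmt(card.density)
        elif card.model == "rigid":
            etree.SubElement(m, "density").text = "1"

    geo = etree.SubElement(root, "Geometry")
    node_offset: dict[str, int] = {}
    offset = 0
    for pname, part in model.parts.items():
        node_offset[pname] = offset
        nodes = etree.SubElement(geo, "Nodes", name=pname)
        for i, p in enumerate(part.vertices, start=1):
            n = etree.SubElement(nodes, "node", id=str(offset + i))
            n.text = f"{_fmt(p[0])},{_fmt(p[1])},{_fmt(p[2])}"
        offset += part.n_vertices
    for pname, part in model.parts.items():
        mat_id = mat_ids[model.materials[pname]]
        elems = etree.SubElement(geo, "Elements", type="tet4", mat=str(mat_id), name=pname)
        off = node_offset[pname]
        for i, c in enumerate(part.cells, start=1):
            e = etree.SubElement(elems, "elem", id=str(i))
            e.text = ",".join(str(off + int(x) + 1) for x in c)
    for set_name, (mat_name, nodes) in model.rigid_node_sets.items():
        part = set_name.rsplit("_", 2)[0] + "_cortical"
        ns = etree.SubElement(geo, "NodeSet", name=set_name)
        off = node_offset[part]
        for nid in nodes:
            etree.SubElement(ns, "node", id=str(off + int(nid) + 1))
    for part, nodes in model.fixed_nodes.items():
        ns = etree.SubElement(geo, "NodeSet", name=f"fixed_{part}")
        off = node_offset[part]
        for nid in nodes:
            etree.SubElement(ns, "node", id=str(off + int(nid) + 1))

    bnd = etree.SubElement(root, "Boundary")
    for part in model.fixed_nodes:
        fix = etree.SubElement(bnd, "fix", bc="x,y,z", node_set=f"fixed_{part}")

    con = etree.SubElement(root, "Contact")
    for c in model.contacts:
        cc = etree.SubElement(con, "contact", type=_FEB_CONTACT_TYPE[c.kind])
        etree.SubElement(cc, "tolerance").text = _fmt(c.tolerance)
        etree.SubElement(cc, "primary").text = c.primary
        etree.SubElement(cc, "secondary").text = c.secondary

    disc = etree.SubElement(root, "Discrete")
    if model.springs:
        dmat = etree.SubElement(
            disc, "discrete_material", id="1", name="ligament", type="linear spring"
        )
        # k = E A / L per spring; write the mean stiffness as the material E
        # and per-spring geometry in the discrete sets
        card = model.material_cards.get("ligament")
        E_lig = card.E if card else 0.22
        etree.SubElement(dmat, "E").text = _fmt(E_lig)
        for si, (s, (pu, pl)) in enumerate(zip(model.springs, model.spring_coords), start=1):
            dset = etree.SubElement(
                disc,
                "discrete_set",
                name=f"{s.ligament}_{s.part_upper}_{s.part_lower}",
                dmat="1",
            )
            for a, b in zip(pu, pl):
                el = etree.SubElement(dset, "delem")
                el.text = (
                    f"{_fmt(a[0])},{_fmt(a[1])},{_fmt(a[2])},"
                    f"{_fmt(b[0])},{_fmt(b[1])},{_fmt(b[2])}"
                )

    lda = etree.SubElement(root, "LoadData")
    ramp = etree.SubElement(lda, "loadcurve", id="1", type="linear")
    etree.SubElement(ramp, "point").text = "0,0"
    etree.SubElement(ramp, "point").text = "1,1"

    for k, lc in enumerate(model.loads, start=1):
        step = etree.SubElement(root, "Step", name=lc.name)
        ctrl = etree.SubElement(step, "Control")
        etree.SubElement(ctrl, "time_steps").text = str(n_steps)
        etree.SubElement(ctrl, "step_size").text = _fmt(1.0 / n_steps)
        etree.SubElement(ctrl, "analysis", type="static")
        loads_el = etree.SubElement(step, "Loads")
        body = etree.SubElement(
            loads_el, "rigid_body", mat=str(mat_ids.get("rigid_endplate_L1_upper", 0))
        )
        for comp, val in (
            ("Fx", lc.Fx), ("Fy", lc.Fy), ("Fz", lc.Fz),
            ("Mx", lc.Mx), ("My", lc.My), ("Mz", lc.Mz),
        ):
            f = etree.SubElement(body, "force", bc=comp.lower(), lc="1")
            f.text = _fmt(val)

    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")


def parse_feb(path) -> dict:
    """Re-parse an exported FEBio file: counts and coordinates for round-trips."""
    tree = etree.parse(str(path))
    root = tree.getroot()
    out: dict = {"parts": {}, "springs": 0, "contacts": 0, "load_cases": [], "materials": {}}
    for nodes in root.findall(".//Geometry/Nodes"):
        coords = []
        for n in nodes.findall("node"):
            coords.append([float(x) for x in n.text.split(",")])
        out["parts"].setdefault(nodes.get("name"), {})["nodes"] = np.asarray(coords)
    for elems in root.findall(".//Geometry/Elements"):
        cells = []
        for e in elems.findall("elem"):
            cells.append([int(x) for x in e.text.split(",")])
        out["parts"].setdefault(elems.get("name"), {})["cells"] = np.asarray(cells)
    out["springs"] = sum(
        len(ds.findall("delem")) for ds in root.findall(".//Discrete/discrete_set")
    )
    out["contacts"] = len(root.findall(".//Contact/contact"))
    for step in root.findall("Step"):
        case = {"name": step.get("name")}
        for f in step.findall(".//force"):
            case[f.get("bc")] = float(f.text)
        out["load_cases"].append(case)
    for m in root.findall(".//Material/material"):
        props = {c.tag: c.text for c in m}
        out["materials"][m.get("name")] = {"type": m.get("type"), **props}
    return out


# ---------------------------------------------------------------------------
# VTK export
# ---------------------------------------------------------------------------


def export_vtk(model: FEModel, out_dir) -> dict[str, str]:
    """One legacy ASCII VTK unstructured-grid file per part plus a spring
    polyline file; returns the file map."""
    from pathlib import Path

    from .mesh_io import save_vtk_polylines, save_vtk_unstructured

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    for i, (pname, part) in enumerate(model.parts.items()):
        path = out_dir / f"{pname}.vtk"
        save_vtk_unstructured(part, path, part_label=i)
        files[pname] = str(path)
    if model.spring_coords:
        pts = []
        lines = []
        for pu, pl in model.spring_coords:
            for a, b in zip(pu, pl):
                lines.append((len(pts), len(pts) + 1))
                pts.append(a)
                pts.append(b)
        path = out_dir / "springs.vtk"
        save_vtk_polylines(np.asarray(pts), np.asarray(lines), path)
        files["springs"] = str(path)
    return files
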