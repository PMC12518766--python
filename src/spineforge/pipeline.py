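"""End-to-end pipeline: labeled surface meshes -> assembled FE model.

``run_pipeline`` drives the five stages in order — bone split, disc split,
endplate extraction, ligament springs, cartilage fills — and assembles the
result.  All numeric parameters live in :class:`PipelineConfig` and can be
overridden from a JSON configuration file.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from .assembly import FEModel, assemble_model, default_load_cases, default_materials
from .bone_split import BoneSplitParams, split_bone
from .cartilage import DEFAULT_MAX_GAP, build_cartilage, contact_faces, interface_labels
from .disc_split import DEFAULT_NUCLEUS_SCALE, split_disc
from .endplates import EndplateParams, extract_lower_endplate, extract_upper_endplate
from .ligaments import build_segment_springs, default_ligament_table
from .mesh_core import MeshError, SmoothingParams, TriMesh


@dataclass
class PipelineConfig:
    """Every numeric parameter of the pipeline, JSON-overridable."""

    t_core: float = 0.3  # mm cortical thickness
    smoothing_lam: float = 0.5
    smoothing_iterations: int = 10
    nucleus_scale: float = DEFAULT_NUCLEUS_SCALE
    nucleus_point_spacing: float = 1.0  # mm
    boundary_samples: int = 64
    cluster_dist: float = 1.5  # mm
    upper_keep_percentile: float = 70.0
    lower_offset: float = 20.0  # mm
    lower_keep_fraction: float = 0.55
    cartilage_max_gap: float = DEFAULT_MAX_GAP  # mm
    n_springs: int = 10
    pll_closest_n: int = 20
    superior: tuple[float, float, float] = (0.0, 0.0, 1.0)
    anterior: tuple[float, float, float] = (0.0, 1.0, 0.0)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    def bone_params(self) -> BoneSplitParams:
        return BoneSplitParams(
            t_core=self.t_core,
            smoothing=SmoothingParams(self.smoothing_lam, self.smoothing_iterations),
        )

    def endplate_params(self) -> EndplateParams:
        return EndplateParams(
            cluster_dist=self.cluster_dist,
            upper_keep_percentile=self.upper_keep_percentile,
            lower_offset=self.lower_offset,
            lower_keep_fraction=self.lower_keep_fraction,
        )


@dataclass
class PipelineResult:
    model: FEModel
    bones: dict
    discs: dict
    endplates: dict
    cartilage: list
    springs: list
    report: dict = field(default_factory=dict)


def run_pipeline(
    stack: dict[str, TriMesh],
    config: PipelineConfig | None = None,
    verbose: bool = False,
) -> PipelineResult:
    """Run the full preprocessing pipeline on a labeled L*/D* mesh map."""
    config = config or PipelineConfig()
    t_start = time.time()
    levels = sorted((k for k in stack if k.startswith("L")), key=lambda s: int(s[1:]))
    disc_levels = sorted((k for k in stack if k.startswith("D")), key=lambda s: int(s[1:]))
    if not levels:
        raise MeshError("no vertebra meshes (L*) in the input stack")

    def log(msg: str) -> None:
        if verbose:
            print(f"[{time.time() - t_start:7.1f}s] {msg}")

    bones = {}
    endpl = {}
    for lev in levels:
        log(f"bone split {lev}")
        bones[lev] = split_bone(stack[lev], config.bone_params())
        up = extract_upper_endplate(stack[lev], config.endplate_params(), superior=config.superior)
        lo = extract_lower_endplate(
            stack[lev], up, config.endplate_params(), superior=config.superior
        )
        endpl[lev] = {"upper": up, "lower": lo}

    discs = {}
    for lev in disc_levels:
        log(f"disc split {lev}")
        discs[lev] = split_disc(
            stack[lev],
            scale=config.nucleus_scale,
            point_spacing=config.nucleus_point_spacing,
            n_samples=config.boundary_samples,
            superior=config.superior,
            anterior=config.anterior,
        )

    springs = []
    spring_coords = []
    table = default_ligament_table()
    for spec in table:
        spec.n_springs = config.n_springs
        spec.closest_n = config.pll_closest_n
    for upper, lower in zip(levels[:-1], levels[1:]):
        log(f"ligaments {upper}-{lower}")
        sets = build_segment_springs(
            upper, stack[upper], lower, stack[lower], table=table, anterior=config.anterior
        )
        for s in sets:
            springs.append(s)
            spring_coords.append(
                (stack[upper].vertices[s.nodes_upper], stack[lower].vertices[s.nodes_lower])
            )

    cartilage = []
    for label, lev, side, dlev in interface_labels(len(levels)):
        if dlev not in discs:
            continue
        log(f"cartilage {label}")
        patch = endpl[lev][side]
        part = discs[dlev]
        nuc_sel = contact_faces(
            part.nucleus_mesh, patch, stack[lev], max_gap=config.cartilage_max_gap
        )
        ann_sel = contact_faces(
            part.annulus_mesh, patch, stack[lev], max_gap=config.cartilage_max_gap
        )
        cartilage.append(
            build_cartilage(
                patch,
                stack[lev],
                part.nucleus_mesh,
                nuc_sel,
                annulus_part=part.annulus_mesh,
                annulus_contact=ann_sel,
                label=label,
            )
        )

    log("assembling model")
    model = assemble_model(
        bones=bones,
        discs=discs,
        cartilage=cartilage,
        springs=springs,
        spring_coords=spring_coords,
        endplates=endpl,
        vertebra_surfaces={lev: stack[lev] for lev in levels},
        materials=default_materials(),
        loads=default_load_cases(),
    )
    from .mesh_core import enclosed_volume

    report = {
        "n_parts": len(model.parts),
        "n_springs": model.total_springs(),
        "n_contacts": len(model.contacts),
        "cartilage_labels": [c.label for c in cartilage],
        "bone_volume_error_pct": {
            lev: 100.0
            * abs(
                bones[lev].cortical_shell.volume()
                + bones[lev].cancellous_core.volume()
                - enclosed_volume(stack[lev])
            )
            / enclosed_volume(stack[lev])
            for lev in levels
        },
        "disc_volume_error_pct": {
            lev: 100.0
            * abs(
                discs[lev].nucleus_solid.volume()
                + discs[lev].annulus_solid.volume()
                - enclosed_volume(stack[lev])
            )
            / enclosed_volume(stack[lev])
            for lev in disc_levels
        },
        "runtime_s": time.time() - t_start,
    }
    return PipelineResult(
        model=model,
        bones=bones,
        discs=discs,
        endplates=endpl,
        cartilage=cartilage,
        springs=springs,
        report=report,
    )
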