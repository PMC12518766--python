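# spineforge

Automated preprocessing for patient-specific lumbar-spine finite-element
models.  Given labeled triangulated surface meshes of the five lumbar
vertebrae (L1–L5) and the four intervertebral discs (D1–D4) — as exported by
any CT segmentation tool, in millimetres — `spineforge` produces a complete,
simulation-ready FE model: cortical shell and cancellous core per vertebra,
nucleus pulposus and annulus fibrosus per disc, vertebral endplate patches,
cartilage volumes filling every vertebra–disc gap, spring-element ligaments,
material cards, contact definitions, boundary conditions and physiological
load cases, exported as FEBio-format XML and legacy ASCII VTK.

It is aimed at biomechanics researchers who want to go from segmentation to a
solvable model without manual meshing, and it ships a deterministic synthetic
lumbar-stack generator so the entire pipeline can be exercised and tested
with no patient data.

## The geometry processing at its core

* **Cortical/cancellous split.** For a vertebra surface M = (V, F), face
  normals N_f = (v2−v1)×(v3−v1)/‖·‖ are averaged (area-weighted) to vertex
  normals n(v), and the cancellous surface is the inward offset
  V_cancellous = V_cortical − t_core·n(v) with uniform cortical thickness
  t_core = 0.3 mm, regularized by synchronous Laplacian smoothing
  vᵢ ← (1−λ)vᵢ + λ·mean(neighbours), 0 < λ ≤ 1.  Both nested surfaces are
  volume-meshed in a single conforming tetrahedralization; cells are
  classified by centroid containment, so shell and core share interface
  nodes exactly.
* **Nucleus/annulus split.** PCA of the disc vertices (covariance with
  1/(n−1)) gives axes u1, u2, u3 by descending variance; the disc outline is
  projected onto the (u1, u2) plane, traced as a concave hull, resampled at
  equal arc length, shrunk about its centroid by the nucleus scale factor
  (C_nucleus = s·C_disc, default s = 0.6), extruded along u3 and clipped to
  the disc.  Disc faces with at least one vertex inside that solid are
  nucleus faces, the rest annulus; a lofted wall closes both into watertight
  solids that share the interface geometry.
* **Endplates.** The least-variance principal axis L separates up- from
  down-facing faces; candidates above the mid height z > (max z + min z)/2
  are single-linkage clustered at 1.5 mm, the largest cluster is kept and
  radially shrunk — upper: keep in-plane radii rᵢ = √((xᵢ−Cx)² + (yᵢ−Cy)²)
  up to the linearly interpolated 70th percentile; lower: candidates beyond a
  parallel plane 20 mm below the upper plane, keep rᵢ ≤ 0.55·max r.
* **Ligaments.** Attachment areas come from cutting planes through the
  vertebral centroid O with normals from spherical coordinates
  N = r(sin φ cos θ, sin φ sin θ, cos φ); vertices with N·(P−O) > 0 attach.
  The built-in table covers ALL, ITL (left/right), CL (four points), SSL/ISL,
  PLL (closest-N posterior points) and LF (midpoints between vertebral
  centers); each ligament instance becomes 10 linear springs (E = 0.22 MPa).
* **Materials and loads.** Cortical bone E = 12 000 MPa/ν = 0.3, cancellous
  E = 100/ν = 0.2, nucleus Mooney–Rivlin (c1 = 0.12, c2 = 0.09,
  k = 666.67 MPa), annulus (c1 = 0.56, c2 = 0.14, k = 14.89 MPa), cartilage
  E = 23.8/ν = 0.4.  Load cases: extension Mx = −7.5 N·m, Fz = −50 N;
  flexion Mx = 7.5, Fz = −117.5; axial rotation Mz = 5.5, Fz = −72; lateral
  bending My = 7.8, Fz = −70 — applied through a rigid body on L1's upper
  endplate while L5's lower endplate is fully constrained.

## Worked example

Generate a synthetic lumbar stack and run the full pipeline:

```sh
spineforge synth --out spine/ --seed 1
spineforge run-all --in spine/ --out model/
```

or equivalently from Python:

```python
from spineforge.synthetic_spine import SpineFixtureParams, make_lumbar_stack
from spineforge.pipeline import run_pipeline

stack = make_lumbar_stack(SpineFixtureParams(seed=1))
res = run_pipeline(stack)
print(res.report["n_parts"], res.report["n_springs"], res.report["n_contacts"])
print({k: round(v, 2) for k, v in res.report["disc_volume_error_pct"].items()})
```

which prints

```
26 320 44
{'D1': 1.19, 'D2': 1.23, 'D3': 1.17, 'D4': 1.12}
```

26 parts are 5 cortical shells + 5 cancellous cores + 4 nuclei + 4 annuli +
8 cartilage segments (labeled L1D1, L2D1, …, L5D4 — one per vertebra–disc
interface).  320 springs are 10 per ligament instance × 8 ligaments × 4
motion segments.  The 44 contacts split into 4 stick (nucleus–annulus),
8 tied (cartilage–endplate) and 32 node-to-surface (ligament attachments).
The per-disc numbers are the volume-conservation error of the
nucleus + annulus solids against the input disc, in percent.
`model/model.feb` holds the assembled FEBio model and `model/vtk/` one
unstructured-grid file per part plus the spring polylines.

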