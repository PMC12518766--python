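# Methods

This note documents the geometric procedures, the parameters that matter,
the synthetic data the tests run on, and the numerical choices made where
the design was genuinely open.  All lengths are millimetres; the declared
anatomical frame is superior = +z, anterior = +y, left = +x.  Every
operation that depends on that frame (PCA sign conventions, posterior
restrictions, endplate light direction) takes the frame as an argument, so
arbitrarily posed inputs can be handled by passing the rotated frame — this
is the frame-alignment pre-step the CLI assumes has happened upstream.

## Mesh primitives

**Normals.** Face normals follow the right-hand rule on the stored winding.
The inward-offset direction is the *area-weighted vertex normal* — the
per-face rule applied at a vertex is ill-defined where faces meet, while the
area-weighted mean is defined everywhere and reduces to the face normal on
flat patches.  Faces with area below 1e-10 mm² are removed at load time so
no zero-length normal can arise.

**Laplacian smoothing** is synchronous (Jacobi-style): each iteration
computes every update from the previous iterate, so results are independent
of vertex order and reproducible.  The update is
v ← (1−λ)v + λ·centroid(1-ring), λ ∈ (0, 1], default λ = 0.5 with 10
iterations.  The iteration count is not prescribed anywhere authoritative;
the default removes offset artifacts on all shipped fixtures and both values
are exposed in the configuration.

**Containment** (`point_in_mesh`) casts a +z ray per query point against
candidate faces from a 2D grid over face footprints and takes crossing
parity; rays that graze a triangle edge or vertex fall back to the
generalized winding number.  Points within 1e-9 mm of the surface classify
as *inside* — a fixed convention so downstream face classification is
deterministic.  Tests compare against an unaccelerated all-faces ray-parity
oracle.

**Isotropic remeshing** is the classic split-long / collapse-short /
flip-valence / tangential-relax loop with projection back to the input
surface (target band 4/5·ℓ to 4/3·ℓ).  Contract: median edge within 25% of
the target and volume preserved within 1% when refining; coarsening a
curved surface necessarily loses the facet-sag volume, which the contract
does not cover.

**Tetrahedralization** has no external volume mesher behind it: the interior
is meshed by Delaunay triangulation of the surface vertices plus interior
Steiner points (a grid at the median edge spacing and a thin inward offset
layer that stops cells bridging across concavities such as an annulus ring),
keeping tetrahedra whose centroid is inside the surface.  Total cell volume
is enforced within 1% of the enclosed volume, with up to two bounded
refinement passes.  For convex inputs the boundary equals the input surface
exactly; for concave inputs it approximates the surface while the volume
bound still holds — the boundary faces always form a closed (even-incidence)
cycle, though dropped degenerate slivers from cospherical inputs can leave
coincident zero-volume "pillow" face pairs on it.

## Synthetic lumbar stack

The generator emulates exactly the structural features the pipeline keys
on, not patient statistics.  A vertebra is a star-shaped radial field on an
icosphere: a superellipsoidal body (semi-axes 20 × 15 × 12 mm, exponent 4 so
the endplates are nearly flat like real vertebrae) plus smooth posterior
bumps — one spinous, two transverse, two articular — scaled from the 25 mm
process length.  Star-shaped fields are closed, manifold and
self-intersection-free by construction, which a CSG union could not
guarantee without a boolean engine.  Discs are elliptical rounded cylinders
(18 × 13 × 10 mm) whose caps are tessellated uniformly along the profile so
cap faces have realistic local size.  Seeded low-order smooth noise
(default 0.2 mm) perturbs both, damped to zero at the poles/caps so the
vertebra–disc clearance is governed by the configured 0.5 mm gap.  Default
vertebra refinement is icosphere subdivision 4 (~1 mm edges on the body),
matching the density the 1.5 mm clustering threshold assumes.

The analytic volume oracle integrates the same radius field by spherical
quadrature (V = ⅓∮r³dΩ), independent of the mesh path.

What passing tests on these fixtures does *not* show: robustness to
segmentation defects (holes, non-manifold patches, islands), to strongly
pathological anatomy, or to meshes far coarser/finer than ~1 mm.

## Bone split

Offset by t_core = 0.3 mm along vertex normals, with a thin-region guard:
if a vertex's inward ray meets the opposite surface within 2·t_core, its
offset is clamped to 45% of that distance, preventing inversion at thin
posterior processes (the uniform-thickness model is silent on thin
features).  After smoothing, vertices that crossed the outer surface —
possible in concave creases, where the neighbour centroid lies outside the
body — are re-seated at depth t_core beneath the nearest outer vertex.  The
artifact check is (a) closedness, (b) every core vertex strictly inside the
outer surface, (c) no face fold-over (offset face normal · source face
normal > 0); a full triangle-triangle intersection sweep is not run.  One
retry with 50% more smoothing iterations precedes the error path.

The shell is built by one conforming Delaunay over outer + core vertices,
classifying cells by centroid containment in the core.  This guarantees a
single shared node set at the interface (required by the contact model) and
makes shell + core = outer volume conservation exact by construction.

## Disc split

PCA sign conventions: u3 toward superior, u1 toward anterior, u2 = u3 × u1.
Degenerate eigen-subspaces (circular or spherical clouds) are resolved by
projecting the reference direction onto the tied subspace — deterministic
and exactly axis-aligned for isotropic inputs.

The boundary outline is a 2D alpha shape with α = 2× the median mesh edge
length (convex hull fallback), resampled to equal arc length starting at the
most anterior point.  The default nucleus scale s = 0.6 gives a nucleus
cross-section of ~36% of the disc area, mid-range of reported anatomy; it is
configuration-exposed.

Classification uses the *unclipped* extrusion of the scaled footprint
(extended 5% beyond the disc's axial extent): it strictly contains the disc
surface above/below the footprint, so vertex containment is robust, whereas
the clipped solid's caps lie exactly on the disc surface and would classify
borderline.  The clipped (conforming) solid is available for volume work and
oracle tests.  The extrusion height beyond the disc — 5% of the axial
extent — is a package choice; any value that clears the surface gives the
same partition.

The nucleus/annulus wall is triangulated directly between the original rim
vertex loops of the two face sets: loops are oriented consistently, started
at the nearest pair, and merged monotonically by normalized arc length (a
monotone merge cannot twist, so no edge is created more than twice).
Because the wall uses the original rim vertices, both sub-surfaces close
exactly, interface node coordinates are bitwise identical across the two
solids, and nucleus + annulus surface volumes sum to the disc volume
exactly; the residual error reported by the pipeline comes only from
tetrahedralization.  The equal-count `loft_walls` (cyclic-shift alignment)
remains the mechanism for curves that are already resampled, e.g. cartilage
side walls.  The interface is emitted as coincident duplicated geometry plus
a declared stick-contact pair, satisfying both the shared-node and the
contact reading of the original model; a configuration flag could merge
nodes instead.

## Endplates

The recipe is: orientation filter (face normal · L > 0 for upper), mid-height
threshold, single-linkage clustering at 1.5 mm (implemented as connected
components of the radius graph, equivalent to a single-linkage cut), largest
cluster (ties: larger mean height for the upper plate, lower for the lower),
then radial shrinkage.  The percentile is the linear-interpolation
definition (numpy default) — definitions differ at small n, so it is stated
here.  The lower-endplate candidate set additionally requires
downward-facing incidence; the plane-side rule alone admits lateral-wall
vertices on tall specimens.  The 20 mm lower-plane offset is literal and
configurable; it assumes adult-scale vertebrae taller than 20 mm.

## Ligaments

Table values are interpreted as degrees and millimetres and the conversion
is spherical — the magnitudes (e.g. θ = 156, −85) are only meaningful as
degrees, and the formula is the spherical one even though the table caption
says "cylindrical".  Negative radii are handled algebraically and flip the
selected half-space.  The plane origin is the vertebral centroid (the only
center the recipe defines).  Pairing across a motion segment: lower-labeled
coordinates select on the upper vertebra, upper-labeled on the lower
vertebra.  Spring placement inside an attachment area is farthest-point
sampling seeded at the centroid-nearest vertex — the distribution rule is
otherwise unspecified — and each anchor pairs with its nearest vertex on the
opposite region, rest length = current distance.  PLL uses the 20 closest
posterior vertices per vertebra (N unstated upstream; configurable).  LF
anchors on the 20 posterior vertices nearest the midpoint of adjacent
vertebral centers, so 10 distinct springs exist rather than a single
collapsed point.  Spring stiffness is k = E·A/L with E = 0.22 MPa and a
configurable effective area (default 10 mm² per spring); the E-to-stiffness
conversion is not specified upstream and is documented here as the package's
rule.

## Cartilage

Contact faces are disc faces whose centroid lies within max_gap = 2 mm of
the endplate patch *and* whose outward normal opposes the endplate plane
normal with at least 0.3 cosine margin (excluding tangential interface-wall
faces).  The 2 mm default sits above typical segmentation gaps and below the
disc height.  The cartilage surface is endplate patch + contact faces +
a monotone-merge side wall between their two longest boundary loops;
coincident vertices across the nucleus/annulus blocks are welded, stray face
islands dropped, and boundary pinch vertices (two loops kissing at a vertex)
opened by deleting one incident face before lofting.  Remaining small loops
are centroid-fanned closed.  Labels follow L\<k\>D\<j\> (both endplate sides of
every disc), eight segments for five levels.

## Assembly and export

Contacts are auto-generated: stick per nucleus–annulus pair, tied per
cartilage–cortical interface, node-to-surface per ligament attachment.  The
fixed boundary condition takes every cortical node coincident with the
lowest vertebra's lower endplate patch; loads bind to a rigid body on the
highest vertebra's upper endplate.  "Stick" maps to the FEBio `sticky`
contact, "tied" to `tied`, "node_to_surface" to `sliding-node-on-facet`;
the 0.01 mm node tolerance is written on every contact.  Loading is
quasi-static with 10 equal increments per case (the increment count is a
package default).  Node coordinates are written with 12 significant digits
so the export/import round trip stays below 1e-9 relative error.

## Problem sizes and tolerances

The shipped test and acceptance runs use the generator defaults: subdivision-4
vertebrae (2562 vertices), 48 × 12 discs, five levels.  Volume-conservation
contracts: shell + core within 2% (exact by construction here),
nucleus + annulus solids within 3% (≈1.2% measured), tetrahedral volume
within 1% of the enclosed volume, offset radius on the reference sphere
within 0.05 mm.  Degenerate inputs (open meshes, empty candidate sets,
coincident centers, sub-3-point clouds) raise `MeshError` with the offending
indices rather than propagating bad geometry.

## Known limitations

* Tetrahedral quality is not optimized (no sliver removal beyond the volume
  filter); meshes are geometry-faithful but not solver-tuned.
* The annulus has no fiber-reinforced substructure; ligaments are linear
  springs without a toe region.
* Cortical thickness is uniform and purely geometric — no density-based
  (Hounsfield) mapping.
* The FE solve itself (range of motion, stress fields) is out of scope; the
  exporter targets FEBio-format XML (spec 2.5) but no solver run is
  attempted here.
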