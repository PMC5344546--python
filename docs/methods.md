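# Methods

## Scope and model

`discfem` models a single ovine lumbar intervertebral disc as a hexahedral
finite-element continuum and asks which stress state a complex loading
scenario produces in the annulus fibrosus (AF), and how well those stresses
predict the failures observed in matched in vitro specimens. The pipeline
has five stages: parametric mesh generation, nucleus swelling
initialisation, quasi-static loading, regional tensile-stress averaging,
and a statistical failure analysis (damage scoring, stress-score
regression, threshold classification).

## Constitutive models

Three behaviours cover the disc tissues (parameters in MPa, region defaults
in `constitutive.OVINE_MATERIALS`):

* **Annulus fibrosus** — Holzapfel–Gasser–Ogden strain energy with two
  dispersed fibre families:
  Ψ = C10(Ī₁−3) + (1/D)((J²−1)/2 − ln J)
  + (K1/2K2) Σ_α [exp(K2 ⟨Ē_α⟩²) − 1],
  Ē_α = κ(Ī₁−3) + (1−3κ)(Ī₄α−1). The Macaulay bracket keeps fibres
  tension-only. The anterior, lateral and posterior AF carry separate
  (C10, D, K1, K2, κ) sets. The cited commercial-solver convention for the
  volumetric term, (1/D)((J²−1)/2 − ln J), is adopted; the exact form used
  originally is not recoverable from the source text, so it is a documented
  convention, not a verified fact.
* **Nucleus pulposus** — nearly incompressible Neo-Hookean (C10 = 0.16779,
  D = 0.12), same volumetric term for consistency.
* **Endplates** — the cartilaginous (E = 24 MPa, ν = 0.4) and bony
  (E = 1000 MPa, ν = 0.3) endplates are "linear elastic" in the source
  description. They are implemented as a compressible Neo-Hookean solid
  with the corresponding Lamé constants,
  Ψ = μ/2(I₁−3) − μ ln J + λ/2(ln J)², which reduces exactly to Hooke's law
  in the small-strain limit and is objective. A Saint Venant–Kirchhoff
  implementation was tried first and abandoned: under the double-
  physiological rotations the 0.1 mm cartilaginous layer is compressed
  through the thickness beyond stretch 1/√3, where SVK loses ellipticity
  and the layer collapses materially, stalling any solver. The chosen form
  keeps the stiffness elliptic at all compressive stretches. This matters
  only at severe compression; in the small-strain regime the two coincide.

A numerical guard caps the fibre exponent K2⟨Ē⟩² at 400 so that trial
states visited by the solvers cannot overflow to non-finite stress; the cap
is unreachable at any equilibrium state of interest (it corresponds to
fibre strains far beyond rupture).

## Geometry

The cross-section outline is a superellipse (exponent 2.5 by default)
through the lateral width (30 mm) and antero-posterior depth (22 mm). The
disc-core height interpolates linearly from the anterior annulus height
(4.5 mm) to the posterior one (2.5 mm). The nucleus boundary is the outer
contour scaled by √(area fraction) (default fraction 0.44) and shifted
posteriorly by 5% of the depth, consistent with the thinner posterior
annulus. The in-plane mesh is a butterfly O-grid (square core, nucleus
transition rings, annulus rings); the axial stack is bony endplate
(0.5 mm) / cartilaginous endplate (0.1 mm) / disc core / CEP / BEP. The CEP
caps the nucleus and inner annulus; over the outer annulus rim the thin cap
layer is bony (a vertebral-rim approximation) so that the annulus height
matches the configured values exactly. The default resolution gives 672
hexahedra; `synthetic.MINI_DISC_RESOLUTION` gives a 196-element disc for
verification runs.

Each annulus element carries two unit fibre directions at ±30° to its
local circumferential axis in the circumferential–axial plane. The ±30°
default is the conventional lamellar value; the angles actually calibrated
for the original model are not published, so the angle is an exposed
parameter, not a reproduction. Local (circumferential, radial, axial)
frames come from the superellipse normal at each element centroid.

Boundary polygons inscribe the smooth contour, so the total volume grows
slightly under refinement (~2% from the default 16-sector resolution to
32); between 32 and 64 sectors the change is below 1%.

## Solvers

Trilinear hexahedra with an F-bar treatment (centroid Jacobian replaces the
Gauss-point Jacobian in the constitutive call) control volumetric locking
of the nearly incompressible tissues; affine fields are reproduced exactly,
so the patch test passes to machine precision. Element tangents are central
finite differences of the element internal force (step 1e-5 mm), assembled
sparse; this is consistent with F-bar and the swelling eigenstrain by
construction.

The caudal surface is fixed; the cranial surface is rigidly coupled to a
reference node at its centroid. All active rotation components (flexion
about −x, lateral bending about +y, axial rotation about +z) are composed
into a single rotation vector and ramped proportionally with the axial
force, which is a dead load along −z: the source protocol states no
ordering, and simultaneous ramping is the order-free choice. The sign
conventions put the stretched postero-lateral sectors on the −x side.

*Implicit mode* (default): Newton iteration with a Levenberg–Marquardt
diagonal shift adapted from the step outcome (the shift only alters the
iteration path, never the converged equilibrium), a kinematic predictor
that spreads each increment's rigid cranial motion linearly through the
disc height, increment halving down to 1/64 of the base increment on
failure, and relative residual tolerance 1e-6. Default 20 increments.

*Explicit mode*: dynamic relaxation — central differences with
Gershgorin-based mass scaling (safety factor, periodic re-estimation,
masses only ever increase), viscous damping (default 0.08 per step), and a
smooth-step load ramp. If a step produces inadmissible kinematics the step
is rewound, velocities are zeroed and the mass scaling quadrupled. In this
mode near-degenerate deformation gradients are repaired by clamping their
principal stretches at 0.25 (invertible-element treatment) so the dynamics
can traverse local snap-through events; converged end states are checked
admissible. The quasi-static criterion is the maximum kinetic/total energy
ratio over the ramp, accepted below 10%.

Equilibrium bookkeeping is exact by construction: the assembled internal
force sums to zero over each element (partition of unity), so caudal
reactions balance the applied load to the Newton tolerance.

## Swelling initialisation

The nucleus is pre-pressurised by an isotropic swelling eigenstrain: NP
material points see the elastic deformation F/s, s ≥ 1. The scalar s is
found by a secant iteration (each evaluation a full equilibrium solve with
the eigenstrain ramped over 4 increments) so that the volume-averaged NP
hydrostatic pressure −tr(σ)/3 with no external load reaches the target,
0.2 MPa by default, within 2%. "Initial pressure" is interpreted as the
volume-averaged mean stress; peak or pore-pressure readings would be
alternatives the source does not disambiguate. The balancing annulus hoop
tension (pressurised-vessel behaviour) is a verified property. All loading
scenarios start from this pre-stressed state, which also stabilises the
annulus wall against the lateral crush of the large bending angles.

## Sectioning and regional averages

Four angular sectors of the annulus are analysed: POST (±20° about the
posterior midline), POST-LAT1 and POST-LAT2 (adjacent 25° sectors on the
side stretched by the lateral bending), and ANT (±20° about the anterior
midline). The printed sector figure has no angles; these extents are
configurable defaults. Each sector splits into cranial/middle/caudal
thirds and inner/outer radial halves — six subsections — by the element
layer and ring indices recorded at meshing. For each subsection and each
local direction (axial, circumferential, radial) the Macaulay-positive
part of the normal stress is volume-averaged over the full subsection
volume; averaging only over tensile elements is available behind a flag.
Marginal rows (cranial/middle/caudal/inner/outer) are volume-weighted
combinations of the subsections by construction.

The annulus–endplate interface stress is the axial resultant of the
internal nodal forces of a sector's annulus elements at the caudal
interface level, divided by the sector's reference patch area, tension
positive. The caudal side is the default because the experimental
endplate failures were read there.

The pure-load stress bound (< 4 MPa for compression, axial rotation or
lateral bending alone) is a POST-section quantity: the published pure-load
figures report that section, and under the double-physiological 4° twist
the postero-lateral outer annulus of a coarse model carries locally much
higher circumferential fibre tension, which that bound was never meant to
cover.

## Failure analysis

The damage score weighs large annulus/endplate-junction failures 1.0 and
small ones 0.5 and sums them. The printed score formula lists the four
terms unweighted while the protocol text assigns 0.5 to small failures;
only the weighted reading reproduces the published group totals
(12, 8.5, 7.5, 4.5, 0), so the weighted form is implemented. Group counts
ship as a package fixture and are expanded deterministically into
per-specimen indicator rows (six specimens per group) whose scores sum to
the group totals.

Regression: per-predictor ordinary least squares of the damage score on
each regional stress, two-sided t-test on the slope, α = 0.05, no
multiplicity correction by default (matching per-cell significance
reporting); a joint multiple regression and Benjamini–Hochberg correction
are available behind flags. All specimens of a scenario share that
scenario's predicted stresses — the design has only five distinct stress
points, a stated limitation of the original protocol as well.

Risk classification uses the empirically identified thresholds: axial
10/6 MPa and circumferential 9/6 MPa for high/low risk, and a single
3.5 MPa high-risk threshold at the interface.

## Synthetic specimens

The generator draws per-specimen failure indicators as independent
Bernoulli variables with logistic probabilities in a stress predictor:
large/small annulus failures follow the axial stress (locations 10 and
6 MPa — the risk thresholds — scale 1.5 MPa), endplate failures follow the
interface stress (locations 3.5 and 2.5 MPa, scale 0.8 MPa). A large
failure supersedes a small one of the same type. With scenario stresses
spanning roughly 3–13 MPa this makes the highest-loaded group fail almost
surely and the flexion-free group almost never, which is what the
generator is meant to emulate.

What the generator does not capture: specimen-to-specimen geometric and
material variability (all specimens of a group share one predicted stress),
correlated failure modes, and any time/cycle dependence. Consequently,
passing the recovery tests shows the statistical pipeline detects a planted
monotone stress–failure link at the experimental cohort size; it does not
validate the biological failure process. With six specimens per group the
sampling noise of adjacent group scores exceeds their expected gaps (the
experimental totals 8.5 vs 7.5 differ by one small failure), so a strict
five-way ordering of simulated group scores is not a statistically
attainable event; the tests assert the stable features — strictly ordered
expected scores and correct extremes in ≥95% of replicates.

## Problem sizes and numerical choices

Default analyses run the 672-element disc; verification and
property-based scenario checks run the 168-element mini disc with 10
increments. The published model used a 56k-element CT-derived mesh with
calibrated fibre angles; its absolute stress magnitudes (e.g. 12 MPa
posterior axial stress under the full loading combination) are therefore
not reproduced at this resolution, and the scenario-level checks are
deliberately property-based: orderings across scenarios, the < 4 MPa
pure-load bound, the 10% kinetic-energy bound, and oracle agreements.

Other numerical defaults worth knowing: Newton tolerance 1e-6 (relative to
the internal-force norm), tangent finite-difference step 1e-5, swelling
tolerance 2% of the target pressure, explicit mass safety 4 with 20 mass
re-estimations and 5000 steps, stretch repair floor 0.25 (explicit mode
only). Ties in risk classification resolve at the threshold value itself
(a value exactly at a high threshold is high risk).

## Known limitations

No viscoelasticity, poroelasticity, osmotic swelling, damage evolution or
interlamellar radial fibres — all outside the scope of the underlying
model. The superellipse geometry is an idealisation of the CT-derived
endplate outline. Interface stresses use element-mean stresses of the
annulus side, so sector boundaries carry a discretisation error of order
one element. The explicit mode is a relaxation scheme in pseudo-time: its
kinetic-energy ratio measures closeness to the quasi-static path of this
scheme, not a physical loading rate.
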