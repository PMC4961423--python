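# Methods

`condylefe` models the transient (primary-impact) and quasi-static
(midstance) stress state of the distal condyle of the equine third
metacarpal (MC3) with a subject-specific, CT-density-driven voxel
finite-element pipeline.  This note documents the models, the choices that
were genuinely open, and what the synthetic phantom does and does not
emulate.

## The material chain

Bone stiffness is mapped from image density in four steps:

1. **HU → ash density**, an affine scanner calibration
   (`ash = slope·HU + intercept`, clipped at zero);
2. **ash → apparent density**, division by a constant ash/apparent mass
   ratio;
3. **apparent density → elastic modulus** by the equine condylar power law

   E [MPa] = 9040 ρ<sup>2.35</sup>,   ρ in g/cm³,

   valid up to the 2.47 g/cm³ ceiling observed in dense equine subchondral
   bone (≈ 7.57·10⁴ MPa at the ceiling);
4. **element averaging of the modulus** over the voxel centers inside each
   element.  The order — modulus per voxel, then mean — is load-bearing:
   because ρ^2.35 is convex, an element's averaged modulus is always ≥ the
   modulus of its mean density (Jensen's inequality), and the tests assert
   both the exact equivalence with a brute-force voxel loop and the Jensen
   direction.

Calibration coefficients are configuration, not constants of the science:
real scanner calibrations vary, and the phantom writes HU through a known
affine map (10⁻³ g/cm³ per HU, zero intercept, ash/apparent 0.6) so the
chain can be round-tripped exactly.  Poisson's ratio defaults to 0.3 for
all bone — the one value stated for the dense augmentation elements,
extended for consistency and overridable in the config.

A set of proximal dense elements raises the total model mass to 5 kg, the
effective distal-limb mass participating in impact.  The augmentation
density is *solved* from the mass deficit rather than fixed: its only
purpose is mass bookkeeping (the source description's "500 g/cm³" is a
tuning device, not a material), and the E = 16 GPa / ν = 0.3 augmentation
stiffness is kept.  Total mass lands within 0.1 % of target by
construction and is asserted.

## Phantom geometry

The condyle is constructive solid geometry: a shaft cylinder of radius
`condyle_separation/2 + condyle_radius` capped by two spheres whose
centers lie on the distal end plane, plus an optional elliptic-prism
sagittal ridge.  CSG gives two things an anatomical mesh cannot: a closed
form for the solid volume (cylinder + sphere union − lens, used as a
voxelization oracle at `ridge_height = 0`) and exact mirror symmetry —
the voxel grid is constructed symmetric about the sagittal plane so a
symmetric spec produces a bit-for-bit mirror-symmetric volume.  A cortical
shell (Euclidean-distance transform of the solid) overlays an i.i.d.
normal trabecular core; the osteoarthritic variant adds a spherical
subchondral density increment (default +0.5 g/cm³, radius 0.35·condyle
radius, palmar-medial) for focal sclerosis.  Densities are clipped to
[0, 2.47] g/cm³.

The counterbody (proximal phalanx stand-in) is the negative imprint of the
condylar profile offset by a congruency gap (default 0.5 mm), posed at the
joint angle (default 170°, mid-range of the 165–175° seen at first ground
contact; angles < 180° narrow the dorsal clearance so impact loads the
dorsal aspect).

What the phantom does **not** emulate: trabecular microarchitecture and
anisotropy, cartilage, surface erosion/pitting, realistic cortical
thickness variation, and specimen-specific anatomy.  Passing tests
therefore demonstrate correctness of the *pipeline* (mapping, solvers,
regionalization) under controlled geometry, not fidelity to any individual
bone.

## Meshing and regions

Meshes are voxel meshes: one axis-aligned hex8 per occupied voxel block
(block occupied at ≥ 50 % mask fill), boundary facets where a face has no
neighbour.  Hex8 with full 2×2×2 integration was chosen over the
quadratic tetrahedra a commercial pipeline would use because voxel hexes
are robust to build, exactly volume-conserving, and make point location
O(1); the convergence harness quantifies the discretization error this
trades in, in the same ±5 % regional-average terms a mesh-refinement study
uses.  A conforming 6-tet split (all cubes sharing the same main diagonal,
so neighbouring face diagonals coincide) is available for export.

The distal articular surface (facets above a configurable z-fraction,
default 0.7, not facing proximally) is partitioned into the standard nine
condylar regions: dorsal/palmar × medial/lateral condyle and parasagittal
groove, plus the sagittal-ridge band.  The source imagery defines these
regions pictorially, not metrically; here the bands are mediolateral
intervals with half-widths defaulting to 0.25 (SR) and 0.5 (PSG outer) of
the condyle separation, ties at a band edge going to SR.  Mediolateral
analysis slices sit ±5 mm (configurable) from the transverse-ridge plane.

## Static (midstance) solve

Small-strain isotropic elasticity; sparse symmetric assembly, one
reference element stiffness per Poisson ratio scaled by each element's
modulus; direct sparse LU below 150 k DOF, Jacobi-preconditioned CG above;
relative residual ≤ 10⁻⁸ enforced.  Loading is 19.5 MPa (mid-range of the
~19–20 MPa ex-vivo midstance joint pressures) applied along the inward
normal on the dorsal and palmar articular patches, with the proximal cut
end fully fixed.  The exact magnitudes and footprints of the original
static loads are not published; they are configuration, and no comparison
in this package depends on their absolute value (see below).  Stresses are
element-centroid values; von Mises is the reported invariant.

Verification: uniaxial bar against pL/E and σ = p (≤ 1 %), patch test
(constant stress to 10⁻⁸), rigid-body motion stress-free, strain energy
against an independent quadrature oracle, global equilibrium of reactions.

## Explicit impact solve

Central-difference (leapfrog) integration with equal-split lumped mass.
Every condyle node starts at 3.55 m/s directed distally; the counterbody's
distal end is fixed.  The time step is the CFL bound on the dilatational
wave speed √(E(1−ν)/(ρ(1+ν)(1−2ν))) with safety 0.8, further capped at
~25 steps per contact-spring period (including a slope allowance, below).
The 0.25 ms interval named by the study is interpreted — and logged — as
the *output/recording* interval; it is three orders of magnitude above any
stable explicit step at sub-millimetre elements.

Contact is node-to-surface penalty contact with the linear
pressure–overclosure law (12 MPa/mm) and Coulomb friction (μ = 0.007)
via an elastic-predictor/slip return mapping with dissipation tracking.
Three numerical choices matter and were learned the hard way (each
previously produced multi-×-KE energy drift):

* **Continuous master surface.** The counterbody surface facing the
  condyle is reduced to one facet per (x, y) grid column (the lowest facet
  initially above the condyle in that column — side walls and rim facets,
  which a vertical penalty cannot represent, are excluded, and excluded
  columns are filled from their lowest valid neighbour).  The contact
  height field is the *bilinear interpolation* of these column heights and
  their deformation; a raw staircase surface injects O(voxel) overclosure
  jumps into laterally sliding nodes and pumps energy.
* **Conservative slope force.** With U = ½kA(z − H(x, y))², the slave
  node feels the full gradient — including the tangential component
  kAg·∇H on sloped surfaces (ridge flanks).  Omitting it makes the spring
  non-conservative under sliding.
* **Rest-clearance calibration.** Voxelization and height-field smoothing
  leave some nodes nominally "inside" the counterbody at t = 0 even
  though the continuum bodies are separated by the congruency gap; a
  per-node rest clearance measured once at t = 0 makes contact respond to
  *advance* only.  Pre-contact free flight is exact by construction (the
  internal force of a rigid translation is skipped, not computed noisily).

With these, the frictionless energy balance over the full 3 ms event
closes to ~10⁻³ of the initial kinetic energy, and a mirror-symmetric
frictionless impact loads medial and lateral regions identically to ~10⁻⁴.
The solver aborts when total energy exceeds 10× the initial KE.  The
interpenetration guard defaults to 10 element edges, not one: with the
soft 12 MPa/mm law and 5 kg of effective mass, the *physical* equilibrium
overclosure at these contact footprints is several millimetres, standing
in for the compliance of the omitted cartilage.

Verification: the elastic-rod rigid-wall impact plateau against
ρcv₀ = v₀√(Eρ) (≈ 20.08 MPa at E = 16 GPa, ρ = 2000 kg/m³,
v₀ = 3.55 m/s), momentum before contact, bit-exact determinism, and
< 1 % change of peak stress under time-step halving.

## Regional analysis

A corner-anchored 8 × 20 grid of 160 equidistant points spans the bounding
rectangle of the domain — either the articular surface footprint or a
mediolateral slice — scaled to the domain's extent.  Points outside the
bone outline are projected to the nearest interior location and counted;
on a domed slice the top grid row necessarily projects (~10 % of points on
the default phantom), an unavoidable property of a rectangular grid over a
curved section.  Sampling is piecewise-constant from element centroids,
consistent with per-element stress output.  Impact stress fields are
evaluated at the recorded frame of peak total contact force — a sampling
instant, as an image-based analysis would use — rather than as a
per-element maximum over every transient wave, which inflates slice
averages several-fold.

Regional tables carry mean, max and count per region; regions without
points are absent, not zero.  The convergence harness meshes the same
phantom at three densities (default coarsenings 4, 3, 2) under the static
load case — cheap enough to refine honestly — and applies the ±5 %
criterion on regional averages of the dorsal slice.  The sensitivity
harness re-runs the impact model with all moduli × 1.5 (strain-rate
stiffening) and reports per-region ratios and the fraction of sample
points that changed.  Variant comparison (healthy vs OA, impact vs
midstance) reports signed absolute and percent differences.

One comparison is deliberately scale-free: whether midstance loads the
palmar aspect more than impact does is tested as an ordering of
palmar/dorsal average-stress *ratios* between the two load cases, because
the absolute static level is set by a configuration pressure whose true
value is unpublished; the ratio form captures the location finding
(impact dorsal, midstance palmar) without depending on it.

## Problem sizes and defaults

The phantom defaults to 0.8 mm voxels (shaft 40 mm, condyle radius 11 mm)
with mesh coarsening 2 (≈ 9 000 condyle elements) — a desk-scale model
for which a 3 ms explicit event takes on the order of a minute, chosen so
that the full pipeline, the three-density convergence study and the
paired-variant comparisons are routinely re-runnable.  The test-suite
solver fixtures use a smaller phantom (1.2 mm voxels, 6 mm condyle) at
coarsening 1, whose exact mirror symmetry supports the symmetry and
energy audits; spacing is a config knob throughout.  Specimen-specific
stress magnitudes are not reproducible without the original scans; all
quantitative guarantees here are oracle-based (closed forms, brute-force
equivalence, conservation laws) or directional.

## Known limitations

* Linear kinematics and linear elastic material everywhere; deep-contact
  states stretch small-strain assumptions locally under the soft penalty.
* The vertical height-field contact cannot transmit load on near-vertical
  surfaces (cup side walls, groove end walls); friction is tangential-
  penalty Coulomb without stick-state hysteresis across separations.
* Master-side tangential reaction of the slope force is not applied (the
  height field is anchored to a spatial grid), so lateral momentum is not
  exactly conserved during oblique contact; energy is.
* Voxel meshes have stair-cased surfaces; facet areas overestimate curved
  surface areas by up to ~√3 locally; the regional comparisons are
  area-weighted consistently, so relative statements are unaffected.
* One RNG stream per phantom volume; healthy and OA variants built from
  the same seed share their trabecular noise realization, making
  variant differences paired rather than independent.
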