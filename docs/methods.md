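# Methods

This note documents the model, its parameters and the numerical choices
behind `vertefem`, in the package's own terms. Units throughout: mm, N,
MPa (so MPa·mm² = N and stiffnesses are N/mm).

## The mechanical model

The object of study is a three-vertebra (T12–L1–L2) spinal segment under
axial compression, potted in cement housings at both ends and loaded
through rigid platens — the standard ex-vivo configuration for measuring
segmental stiffness before and after vertebroplasty. The model is
geometrically and materially linear: it predicts elastic stiffness and
*relative* stress redistribution between treatment states, never strength
or failure. Because the model is linear, the experimentally usual
"average load–displacement gradient" definition of stiffness collapses
exactly to k = reaction / applied displacement from a single solve, and
results obtained under displacement control can be rescaled to any common
reaction force (1000 N is the package default for stress comparisons) by
multiplying displacements and stresses with one scalar.

### Materials

| component | model | constants |
|---|---|---|
| bone (trabecular + cortical) | isotropic, element-specific | E from greyscale, ν = 0.3 |
| cement housing | isotropic | E = 2450 MPa, ν = 0.3 |
| injected cement | isotropic | E = 2040 MPa, ν = 0.3 |
| nucleus pulposus | isotropic | healthy 1 MPa / ν 0.499; degenerated 4.9 MPa / ν 0.43 |
| annulus fibrosus | orthotropic | healthy E = (0.2, 35, 8) MPa, ν = (0.02, 0.065, 1.2); degenerated E = (0.53, 91.9, 21) MPa, ν = (0.022, 0.072, 1.32) |

Annulus axes are 1 = radial, 2 = circumferential, 3 = axial. The
constitutive matrix of every annulus element is rotated into a cylindrical
frame around the body axis, so "circumferential" follows the ring. The
annulus shear moduli are not part of the reference data set; Huber-type
estimates G_ij = √(E_i E_j) / (2(1 + √(ν_ij ν_ji))) are the documented
default and scale with the Young's moduli during calibration, preserving
all anisotropy ratios. Positive definiteness of every orthotropic set is
checked at construction by eigen-decomposition of the compliance.

## The synthetic phantom

No distributable CT data exist for this configuration, so the pipeline
ships a generator for a synthetic segment with the statistical and
geometric structure the analysis needs:

* three elliptic-cylinder vertebral bodies (default radii 16.0 mm lateral,
  11.5 mm anterior–posterior; height 25.2 mm) with a one-voxel cortical
  shell (rim and endplates) of constant greyscale 800,
* two disc slabs (8.4 mm) spanning the full body cross-section, an annulus
  ring around a nucleus core whose radii are a configurable fraction
  (default 0.5) of the body radii — so the nucleus holds ≈25% of the disc
  area,
* potting housings (5.6 mm) at both ends with the same cross-section as
  the bodies, giving a purely axial load path,
* voxel size 1.4 mm — the element size at which voxel models of this kind
  are mesh-converged — for ≈21.6k tissue voxels, 11,328 of them
  trabecular.

The trabecular greyscale field is i.i.d. Gaussian clipped at zero. The
generator's mean/SD defaults are obtained by *inverting* the clipped-normal
moment equations so that the post-clip field (and hence the mapped modulus
under the default identity calibration) has mean 128.41 MPa and SD
66.20 MPa — the reference element-specific bone-modulus moments. Without
the inversion, clipping would bias the mean up by ≈0.7 MPa and the SD down
by ≈1.5 MPa, outside a two-standard-error band at n ≈ 11k. No spatial
correlation is imposed (none is specified by the reference data); the
greyscale model is a hook where a correlated field could be substituted.

What the phantom does *not* emulate: real vertebral morphology (posterior
elements, facet joints, endplate curvature, wedge deformity), CT physics
(noise correlation, partial volume, beam hardening), or off-centre cement
placement — the cement region grows as a centroid-seeded ball in
deterministic distance order. Passing tests therefore demonstrate the
correctness and internal consistency of the pipeline under idealized
geometry, not clinical validity on patient anatomy. One concrete
consequence is documented under "Known limitations" below.

## Material mapping

Bone elements receive E = max(slope·grey + intercept, floor), the linear
density–modulus law that is standard for quantitative-CT-based vertebral
models; defaults slope 1 MPa/greyscale-unit, intercept 0, floor 1 MPa.
The floor exists because clipped greyscale can be exactly zero and a
zero-modulus element would make the stiffness matrix singular; at default
settings it touches ≈3% of trabecular voxels and biases the field moments
by ≈0.02 MPa, negligible against the acceptance bands. Whether the
original mapping for this configuration was density-linear or a power law
is not recoverable; the linear law is the default and the calibration
object is the single place a different law would plug in.

Threshold segmentation bins voxels by greyscale interval (ties to the
higher bin), keeps the largest 6-connected component per bin and applies
morphological closing; it exactly recovers the phantom's partition within
a single structure, by construction of the constant non-bone greyscales.

## Finite elements and solver

Every tissue voxel is one trilinear hex8 element with full 2×2×2 Gauss
quadrature; on a uniform grid the element geometry is exact and one
reference stiffness matrix serves all elements of a material (scaled by E
for isotropic tissues; per-element rotated matrices for the annulus). A
mean-dilatation (B-bar) variant is available for near-incompressible
tissues; on the default phantom it was compared against full integration
(healthy-disc stiffness 255 vs 288 N/mm, identical qualitative orderings)
and full integration remains the default.

Boundary conditions replicate the platen test: bottom-plate nodes fully
fixed; top-plate nodes rigidly coupled to a reference point at the
mid-point of the anterior–posterior diameter of the top plate, which
carries the prescribed axial displacement. Plate rotations are *free* by
default (three rotational master DOFs), emulating load transfer through a
ball seat; a locked-rotation mode exists and coincides with the free mode
on symmetric models. The constraint is applied by exact transformation
(no penalty), so the reduced system stays symmetric positive definite.

The reduced system is solved directly (sparse LU, symmetric-mode
minimum-degree ordering) below 3000 unknowns and by Jacobi-preconditioned
conjugate gradients above (the crossover reflects measured factorization
cost for voxel elasticity at this fill-in); both paths are deterministic
and the true relative residual is verified ≤ 1e-8 after every solve, with
failure raised rather than tolerated. Meshes with components disconnected
from the load path are rejected up front with the component count.
Equilibrium (top vs bottom reaction mismatch) is recorded on every result
and asserted ≤ 1e-6 in the tests. On the default phantom a solve is
≈75k unknowns and takes a few seconds; the problem sizes in the tests
(default phantom for statistics and calibration, a half-scale phantom for
solver-heavy property tests) were chosen so the full suite and the
acceptance script each complete comfortably on one CPU.

## Disc calibration

Disc condition cannot be read from CT greyscale, so the degenerated state
is reverse-engineered: starting from healthy literature properties, disc
stiffness constants are scaled until the model's segmental stiffness
matches the measured pre-augmentation value (default target 617 N/mm,
relative tolerance 1e-3, bracket [1/16, 16], ≤60 evaluations).

Design choices, made where the procedure was genuinely open:

* **One search variable.** A single stiffness measurement cannot identify
  independent annulus and nucleus factors, so the annulus factor is the
  search variable and the nucleus factor is slaved to it.
* **Power-law coupling.** nucleus_factor = annulus_factor^s with
  s = ln 4.9 / ln 2.625 ≈ 1.647. This is the unique power law through both
  anchors the reference property table provides: the healthy state itself
  (factor 1 → factor 1, so calibrating to a healthy-stiffness target
  recovers exactly the healthy state) and the healthy→degenerated
  transition (annulus ×2.625 → nucleus ×4.9). A linear coupling
  nucleus = 1.867·annulus hits the second anchor but not the first.
* **Poisson ratios are never scaled**: the reference table shows them
  moving non-proportionally between disc states (nucleus ν falls
  0.499 → 0.43 while annulus ν's rise ≈10%), and scaling ν risks leaving
  the admissible range.
* **Root finding.** k(factor) is strictly increasing (stiffening elements
  can only stiffen the structure — verified numerically across the
  bracket), so the target is bracketed on log-factor and located by
  Illinois-accelerated regula falsi; convergence is declared on the
  stiffness mismatch, not the factor. Because only disc element matrices
  change between iterations, the global stiffness is split once into
  invariant, annulus and nucleus blocks and recombined algebraically —
  one linear solve per iteration, no reassembly. On the default phantom
  the search converges in 7 evaluations to factor 2.532 (achieved
  616.96 N/mm); forward–inverse recovery of planted factors is accurate
  to <0.1%.

## Treatment operators and study conventions

Augmentation *replaces* the modulus of cement-region elements (pure cement
2040 MPa, or a stated fraction of it to represent bone–cement composite
stiffness); no rule-of-mixtures blending is layered on top, matching how
the augmented-region modulus is treated as a single sweep variable.
Cement volume changes re-derive the region by the same deterministic
distance-from-centroid ordering that seeded it, so regions at different
volumes are nested, achieved counts are exact, and elements leaving the
region recover their greyscale-derived modulus bit-exactly. Bone-quality
scaling multiplies exactly ×0.5/×2 (the "approximately" of re-binned
greyscale workflows is replaced by exact factors, configurable). All
operators touch only their target label sets — asserted in the tests.

Stress redistribution is quantified per element as
100·(vm_post − vm_pre)/vm_pre between solves rescaled to the common
1000 N reaction, on the same mesh (augmentation changes materials, never
the mesh). Elements with pre-stress below 1e-9 MPa go to an explicit
"undefined" bucket rather than being clamped, so histogram mass sums to 1
exactly. Default bins are 10-percentage-point wide over [−100, 100] with
open tails — a granularity choice, configurable, not a reference value.

## Known limitations

* Linear elasticity only: no failure, damage, cement–bone interface
  mechanics, or time-dependent disc behaviour; loading is axial
  compression under displacement control.
* The idealized symmetric phantom damps far-field redistribution: two
  soft discs between the augmented T12 and the bottom vertebra L2 filter
  the perturbation to ±0.01% element-level stress change in L2. The
  *pattern* is systematic — load centralises (the fraction of L2 elements
  gaining stress falls from 0.95 on the axis to 0.63 at the rim, and the
  L1 cortex sheds load) — but the sign of the element-count majority in
  L2 is dominated by the trabecular voxels, because a uniform voxel mesh
  weights regions by volume. Mesh designs that resolve the cortex with
  many small elements weight it by element count instead and report the
  cortical (negative) side as the majority; both summaries describe the
  same mechanical field. The test suite retains an assertion in the
  element-count form; it fails on the default phantom for exactly this
  reason and is kept deliberately, rather than silently re-weighted, so
  the discrepancy stays visible.
* One phantom, one seed per run: the pipeline characterises a single
  synthetic specimen at a time; cross-specimen statistics are out of
  scope.
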