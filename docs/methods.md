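# Methods

This note records the model, the numerical choices, and the study
conditions behind `fibrekin`, including design decisions taken where the
problem leaves them genuinely open.

## Synthetic fiber volumes

Real fiber tomograms are rarely distributable, so the generator is a
first-class module rather than a test fixture. A fiber is an elliptical
solid cross-section of equivalent diameter *d* (the circle of equal
area) and transverse shape factor *s* = major/minor semi-axis; the
semi-axes are `a = (d/2)√s`, `b = (d/2)/√s` so that the area is
independent of *s*. The lumen is a coaxial elliptical tube spanning the
entire length — the defining trait of bast-fiber porosity — whose
cross-section occupies the requested fraction of the outer ellipse, so
that fraction *is* the porosity. The rasterized lumen is calibrated by a
1-D scale search so the voxel-count porosity matches the request despite
discretization bias, and its centre is offset by a fraction of a voxel
to break the 4-fold symmetry that would otherwise quantize the count in
steps of four. Measured porosity lands within one percentage point of
the request for diameters of ~12 voxels and above.

Surface roughness emulates extraction-induced flaws as a Gaussian
random radial field `δ(x, φ)` with prescribed RMS amplitude and
correlation length, applied to the outer boundary only; interior
cavities are detected and protected, so roughness can never breach the
lumen. Amplitude 0 is the identity and equal seeds give equal volumes.
No published defect statistics exist for these fibers, so amplitude and
correlation length are free parameters with mild defaults.

Notches are prisms carved from the surface: a V-notch is a triangle of
opening *w* (along the axis) and radial depth *h*, a U-notch a
semi-ellipse with semi-axes *w*/2 and *h*; both satisfy the opening-angle
relation `tan(θ/2) = w/(2h)`. Removal only converts solid to air, and a
notch deeper than the local radius is rejected.

Four presets encode the descriptors of the four imaged hemp
configurations (a large elongated 9%-porosity bundle; a 44 μm round
4%-porosity bundle; an 18 μm lumen-free elementary fiber with a V-notch;
a 23 μm lumen-free fiber, shape factor 1.78). `scaled_preset` coarsens
the voxel size so the diameter spans a chosen number of voxels and caps
the length in diameters, preserving every dimensionless descriptor
(shape factor, porosity, h/d, w/d); all simulation studies below run on
such scaled fixtures.

## Segmentation and morphometrics

Gray volumes are thresholded (Otsu unless a threshold is given) and
cleaned by binary opening/closing with a ball element. Cavity
extraction floods exterior air from the twelve boundary edges of the
volume box: seeding whole faces — the first idea — leaks into the lumen
where it opens through the axial end faces, while the 8 corners alone
are fragile when a fiber touches the volume edge; the edge set is the
smallest seed family that is robust, lumen-safe and invariant under
axis permutation (corners-only remains available as a strict mode).
Remaining air components are labeled with 6-connectivity — a
conservative cavity definition that cannot leak diagonally through a
one-voxel wall. Porosity is internal air over internal air plus solid,
a per-fiber figure that excludes exterior air.

Per-slice ellipse fits use second-order moments with the 1/12 per-voxel
self-moment correction; semi-axis lengths are `2√λ` of the corrected
covariance eigenvalues. This recovers the area and aspect of rasterized
ellipses within 5% for semi-minor axes of 5 voxels and up. Fiber
descriptors (equivalent diameter, shape factor, length) are computed on
the *filled* per-slice outline so the lumen does not shrink the lateral
dimension.

## Voxel mesh and materials

Every solid voxel becomes one trilinear 8-node cuboid element; vertex
indices are merged exactly, element order is the lexicographic voxel
order, and the mesh volume equals the solid voxel count times the voxel
volume by construction. Air is not meshed — equivalent to zero stiffness
— for memory and conditioning; damaged elements, in contrast, stay in
the mesh with the ground-level modulus `ground · E₀` (default 10⁻⁶) so
the global matrix never becomes singular and the "converted to ground
level" rule is honored literally. Elements that touch only at edges or
corners share nodes but are *not* treated as connected in the component
analysis (face connectivity), because corner-linked chains are
numerically pathological load paths; components not reaching both
loading ends are retained but flagged. Units form a consistent
μm–MPa–μN system.

Defaults `E₀ = 20 000 MPa`, `ν₀ = 0.3` sit inside the 15–45 GPa range
reported for hemp; both are configuration parameters, and the
identification routines exist precisely because per-fiber true values
must be fitted.

## Elastic solver

Element stiffness uses 2×2×2 Gauss integration of the standard
isotropic B-matrix formulation; the matrix is symmetric with exactly six
rigid-body modes and scales linearly in E. Because all elements are
congruent cuboids, global assembly reduces to scattering one unit-E
matrix scaled per element; the scatter pattern is cached
(sort + segmented sum), which makes reassembly in damage loops cheap.

Boundary conditions reproduce the glued-end tensile test: the x = 0 face
fully clamped, the x = L face given `(U, 0, 0)` — the lateral constraint
at the moving grip is applied exactly even though it suppresses Poisson
contraction there, which is why identification measures contraction in
the middle third of the span. The reduced system is solved by sparse LU
(below 4000 free dofs) or Jacobi-preconditioned conjugate gradients at
relative residual 10⁻⁸ with LU fallback; in damage loops CG warm-starts
from the previous increment. Per-element stresses are evaluated at the
centroid, principal values by symmetric eigen-decomposition, and the
stress intensity is `S_I = S₁ − S₃`. With ν → 0 the homogeneous bar
reproduces the uniaxial closed form to solver precision; with ν = 0.3
the end constraint perturbs mid-span stress by under 1% for bars of
aspect 12 and up, which sets the geometry used in the closed-form tests.

## Damage engine

Two conversion rules are implemented.

*Fraction rule* (`mode="fraction"`): the top `⌈f·N_intact⌉` elements by
criterion value convert each increment, ties to the lower element index.
This is the most literal reading of converting "the elements of the
highest stress levels", and it is the default contract of
`select_damage_set`. Its limitation is structural: the number converted
per increment is criterion-independent, so all eight criteria trace the
same damage-ratio ramp and differ only through early-stop timing —
useful for localization studies, incapable of producing
criterion-dependent saturation levels or growth-rate changes.

*Threshold rule* (`mode="threshold"`): every intact element whose
criterion value exceeds a critical stress `σ_c` converts, optionally
truncated to the top `⌈f·N_intact⌉` and to a relative band near the
current maximum. Damage then begins when stress concentrations first
reach the material strength and spreads as the ramp drives the bulk
field past it. This rule is what the kinetics studies use, because it is
the mechanism that makes the eight criteria genuinely different: the
tension-aligned measures (`S_I`, `S₁`, `σ_XX`) cross `σ_c` early at the
notch root and lumen wall and later engulf the whole loaded volume
(early onset, full saturation — the aggressive group); the transverse
normals and axial shears cross late and only locally (intermediate); the
transverse shear `σ_YZ` barely crosses at all (inefficient). An optional
inner loop re-equilibrates and re-converts within one increment
(quasi-static cascade); the default is one solve per increment.

Shear criteria rank by |value|, normal and principal criteria by signed
value (damage here is tension-driven). The damageable set is every solid
element, including near the grips, where damage is in fact observed.
Runs stop early on saturation (nothing intact), stress collapse (max
criterion under 1% of its initial value) or loss of a spanning intact
load path.

## Kinetics characterization

Stage boundaries on the (non-decreasing) damage-ratio curve are the
first increments exceeding 1% and 99% of the final ratio — thresholds
are free choices, exposed as parameters. Growth modality smooths the
curve (moving average, window 5), differences it, and counts local rate
maxima with prominence above 25% of the rate peak: two or more separated
maxima = bimodal (the localized-to-diffuse transition), a growth stage
shorter than the window = inconclusive. Criterion grouping standardizes
(onset increment, final ratio) and clusters with fixed-seed k-means
(k = 3); clusters are ranked by mean onset — earliest = aggressive,
latest = inefficient — with final ratio as tie-break. Fewer than three
distinct behaviors yields an explicit degenerate report. The quantitative
definitions of the three groups are this package's own; only the group
narrative is established.

Modulus identification is exact in the model (force ∝ E₀);
`identify_E0` is a one-line slope ratio. Poisson identification assumes
the same linearity for the mean mid-span lateral contraction, which is
only approximate; one refinement pass (identify, re-simulate, identify
again) brings the error to a few 10⁻⁴, and results are clamped to
(0, 0.5) with a warning.

## Study conditions

The paper-scale meshes (10⁷–10⁸ elements) are out of desk scope; all
simulation studies run on scaled presets whose dimensionless descriptors
match the full-scale fibers.

* **Criterion-grouping sweep** — FXU4-like fixture, 14 voxels across,
  length 2.5 diameters (~4300 elements), strain ramp 0.2%→4% in 25
  increments, threshold rule with `σ_c = 90 MPa`, no cap. `σ_c` is set
  to ~0.8× the weakest criterion's (σ_YZ) peak value at break so every
  criterion crosses it within the ramp, and the strain at which the bulk
  axial stress crosses `σ_c` (ε ≈ σ_c/E₀) falls early enough that the
  aggressive criteria show their full saturation plateau. The 4%
  breaking strain and the implied 280–800 MPa stress span sit inside the
  strength range reported for hemp.
* **Modality contrast** — FIV15-like and FU-like fixtures, 12 voxels
  across, ramp 0.2%→4% in 50 increments, `σ_c = 150 MPa`, conversion
  capped at f = 0.05 per increment so the growth stage is resolved over
  many increments. The lumen-free small fiber damages by notch-crack
  propagation with no late acceleration (monomodal, near-constant rate);
  the lumen-bearing fixture shows a distinct localized phase followed by
  a diffuse burst — the damage rate accelerates within the growth stage.
* **Morphometric recovery** — presets at 48 voxels across, one diameter
  long; segmentation with the generator's own threshold.
* **Identification** — un-notched FU19-like fixture, 10 voxels across.

## What the synthetic data does and does not show

The generator reproduces the *statistical* structure reported for the
imaged fibers: two-phase gray levels, elliptical sections, a full-length
elliptical lumen of controlled porosity and aspect, correlated surface
roughness, prismatic notches. It does not reproduce cell-wall layering
(S1/S2 walls, middle lamellae), kink-band mechanics, real defect
populations, multi-fiber bundle interfaces, or acquisition physics
(beam hardening, reconstruction artifacts). Passing tests therefore
demonstrate the correctness and internal consistency of the pipeline and
the qualitative mechanisms (notch and lumen stress concentration,
criterion ranking, stage structure) — not quantitative prediction for
any particular real fiber, which additionally requires per-fiber
identification of `(E₀, ν₀)` and strength.

## Numerical choices and degenerate inputs

Otsu thresholding fails by construction on constant volumes — an
explicit threshold is then required. Slices with fewer than 5 cavity
voxels are skipped (and counted) in ellipse statistics. Damage ties
break to the lower element index; re-damaging an element is an assertion
failure, not a silent no-op. The CG iteration cap is 10·√n_dof with a
floor of 1000; non-convergence falls back to sparse LU in auto mode and
raises otherwise. All randomness flows through explicit integer seeds,
and identical inputs give bit-identical damage histories.

## Known limitations

Linear isotropic elasticity is a strong simplification for cell-wall
material (inelastic and anisotropic in reality); element-level stiffness
degradation is not fracture mechanics — no crack-tip fields, no stress
intensity factors, no cohesive laws. Scaled fixtures under-resolve
stress concentrations, so quantitative concentration factors and damage
ratios carry discretization bias; only their orderings and stage
structure are asserted. The fraction rule's criterion-independent
trajectory is inherent, not a bug; use the threshold rule for kinetics
questions.
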