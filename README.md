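# fibrekin

Voxel-based finite-element damage kinetics of notched plant bast fibers.

Hemp and other bast fibers fail from surface flaws, machined notches and
their tubular central cavity (the lumen). `fibrekin` re-creates, at desk
scale, the full analysis chain used to study this failure with X-ray
micro-tomography: it generates two-phase voxel volumes of notched fibers
with controlled geometry, segments and quantifies them (porosity, lumen
ellipse statistics, cross-section shape), converts every solid voxel into
an 8-node cuboid finite element, solves the linear elastic tensile
problem, and iterates a stress-criterion damage scheme whose
damage-ratio curves are then characterized (onset / growth / saturation
stages, monomodal vs bimodal growth, criterion ranking).

It is written for researchers in plant-fiber micromechanics and
image-based simulation who want a tested, reproducible reference
implementation of this pipeline rather than a one-off script collection.

## The model

* **Geometry.** The fiber is a two-phase voxel image (air 0 / solid 255),
  X the longitudinal/loading axis. V- and U-notches are triangular or
  semi-elliptical prisms with opening *w* and depth *h*; their opening
  angle is `tan(θ/2) = w / (2h)`.
* **Material mapping.** Each solid voxel becomes one trilinear hexahedral
  element carrying the solid constants `(E₀, ν₀)`; air is not meshed
  (zero stiffness), and a damaged element keeps its place in the mesh
  with a *ground-level* modulus `10⁻⁶·E₀`.
* **Loading.** Glued-end tension: `(Ux,Uy,Uz)|x=0 = (0,0,0)` and
  `(Ux,Uy,Uz)|x=L = (U,0,0)`. Units are μm / MPa / μN.
* **Damage.** At each load increment of a displacement ramp the
  per-element stress state is reduced to one of eight scalar criteria —
  the stress intensity `S_I = S₁ − S₃`, the first principal stress `S₁`,
  the normal components `σ_XX, σ_YY, σ_ZZ` and the shear components
  `σ_XY, σ_XZ, σ_YZ` — and the most stressed intact elements are
  converted to ground level, either a fixed fraction *f* per increment
  or every element whose criterion exceeds a critical stress `σ_c`.
  The damage ratio (damaged / damageable elements) versus increment is
  the damage-kinetics curve.
* **Identification.** The reaction force is strictly proportional to
  `E₀`, so a single trial solve and a slope ratio recover the modulus;
  the mean lateral contraction away from the grips plays the same
  (approximately linear) role for `ν₀`.

## Worked example

`examples/01_generate_and_measure.py` generates the large U-notched
bundle preset (9% porosity, shape factor 3.23, 232 μm lateral dimension)
at 48 voxels across and measures it back:

```
generating: d=232.0 um, shape factor 3.23, porosity 9%, voxel 4.83 um
volume (48, 94, 94) = 4.79e+07 um^3
notch: U, w=60.0 um, h=40.0 um, opening angle 73.7 deg, removed 730 voxels
measured porosity      0.092   (requested 0.09)
measured shape factor  3.30    (requested 3.23)
equivalent diameter    228.6 um (requested 232.0)
lumen ellipse aspect   mean 2.42 / median 2.42
lumen area             mean 3784.5 um^2 / median 3784.5 um^2
```

The measured porosity, shape factor and lateral dimension recover the
generating parameters to within rasterization error — the same
morphometric chain applies unchanged to real segmented tomograms.

`examples/04_identify_constants.py` hides true constants inside a
forward simulation and identifies them back:

```
true  E0 = 31000 MPa   nu0 = 0.360
found E0 = 31002 MPa   nu0 = 0.360
errors: 0.01% and 0.0003
```

The other examples run the tensile solve with its notch stress
concentration (`02_tensile_solve.py`) and the eight-criterion damage
sweep with stage detection and criterion grouping
(`03_damage_kinetics.py`).

## Command line

A thin CLI wraps the library for shell use:

```bash
fibrekin generate --preset FXU4 --seed 7 --out vol.tif
fibrekin segment vol.tif --out seg.tif
fibrekin morph seg.tif --out stats.csv
fibrekin simulate seg.tif --criterion S_1 --out run/
fibrekin analyze run/ --out report.json
fibrekin run --preset FU19 --seed 7 --out run/   # all stages
```

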