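# Methods

This note documents the models, numerical choices and limitations behind
`aortamimic`. Units are mm, N, MPa and seconds throughout; the coordinate
frame is right-handed with x the tensile/length axis and z the print/height
axis.

## Geometry: signed-distance construction

All solids are defined as signed-distance fields (SDFs, negative inside) and
polygonised with marching cubes on a padded grid, so every emitted mesh is
closed and consistently oriented without a Boolean kernel. The default
polygonisation pitch is `strut_thickness / 12` (clamped to 0.01–0.05 mm);
at that pitch the volume of a 0.3 mm round strut is converged to a few
tenths of a percent. When a whole slab is tiled, the hundreds of instanced
copies use a per-design pitch of 0.05–0.08 mm instead, which changes the
design volume fractions by under 0.3 percentage points while keeping the
instanced meshes around a million faces.

The independent volume oracle voxelises the same SDF at 0.05 mm, estimating
each voxel's occupied fraction from signed distances on a 2×2×2 sub-grid
with a clipped linear slab rule. Plain in/out voxel counting is *not* used:
on struts a few voxels across, its grid-phase error reaches +13 % (measured
against a closed-form capsule), whereas the fractional-occupancy estimate is
accurate to ~0.3 %.

### Unit cells

All four cells derive from 5 mm nominal primitives (hexagonal prisms of
circumradius 5 and height 5; 5 mm cubes; the library diamond cell from a
unit cube) and are proportionally rescaled so the nominal cell height equals
the configured `size_z` before the as-printed strut thickness is applied.

* **Chain** — each link is a hexagonal ring drawn at the prism's mid-height
  mark with path circumradius half the prism radius, swept with a *square*
  cross-section of side equal to the configured thickness (an extruded,
  mitred annulus with distance-rounded outer corners). All links in a row
  share one tilt about the row axis, solved so the thickened link exactly
  spans the cell height; consecutive links are placed at pitch
  `(L + d) / 2` with `d = L/3`, so same-orientation links are separated by
  the gap `d` while neighbouring links overlap and interlock. At the default
  design the interlocked solids clear each other by ~0.06 mm — below a
  PolyJet printer's ~0.1 mm accuracy, which is consistent with such chains
  printing as movable but near-touching links. A genuinely perpendicular
  alternate link cannot exist at this cell height (a 0.6 mm ring cannot
  stand upright inside a 1.5 mm cell), which is why the shared-tilt
  chain-mail construction was chosen.
* **Knitted** — one stockinette omega-loop per cell:
  `x = (W/2π)(τ + 1.5 sin 2τ)`, `y = (H/2) cos τ`,
  `z = 0.75 t cos 2τ`, τ ∈ [−π, π], swept with a circular cross-section of
  diameter `t` (yarn is round). The 0.75 t crossing amplitude keeps the two
  strands at a crossing separated by half a thickness.
* **Diamond crystal** — the diamond-cubic beam lattice: 16 struts joining
  the four interior tetrahedral sites of the unit cube to their nearest
  lattice sites, as round capsules of diameter `t`, clipped to the cube so
  adjacent cells connect across faces.
* **Origami (Miura-ori)** — a herringbone triangle-wave mid-surface (one
  corrugation per cell in x, fold lines slanted by the in-plane
  parallelogram angle, default 60°), thickened *along the print direction*
  by `t`. Directional thickening is the standard CAD shell-in-z operation
  for corrugated sheets and makes the cell volume exactly
  footprint × thickness, independent of the fold geometry.

Interpretation constants that the published tessellation table does not pin
down (chain ring radius and cross-section shape, origami thickening
direction) were fixed once so the computed volume fractions land near the
published percentages, and are not exposed as tuning knobs. With the
defaults the four designs occupy 13.1 / 2.8 / 7.6 / 25.0 % of the
64.10 × 10.13 × 2.60 mm slab (published: 12.81 / 3.19 / 7.58 / 25.33 %).
The knitted shortfall is consistent with the printer's behaviour of wrapping
embedded lattices in an extra ~0.6 mm skin of the flexible base resin, which
the as-designed thread does not include.

### Tessellation and embedding

Cells are tiled on a regular grid at pitch = cell extent + spacing per axis
(the chain overrides the x pitch so links stay interlocked); only cells
whose bounding box lies fully inside the slab are kept, giving the count
`floor((dim − extent)/pitch) + 1` per axis, and the grid is centred in the
slab. Because kept cells lie fully inside the slab, the matrix-minus-lattice
Boolean is realised exactly as a cavity: the matrix solid is the slab shell
plus the orientation-inverted lattice shell. Volume additivity
(matrix + lattice = slab) therefore holds to floating-point precision rather
than to a mesh-Boolean tolerance.

### Tubular walls

The vessel wall is parametric: a centerline polyline with an inner-radius
profile, thickened outward by `wall_offset` (default 2 mm) along
angle-weighted vertex normals; offsets that would fold the surface raise an
error. Conformal tessellation maps a planar tiling of the (symmetric)
diamond cell through the tube parameterisation — u along the circumference
and v along the centerline, both at `uv_factor` (default 2.75 mm) of arc
length per cell, with the full circumference covered by a whole number of
cells. The cell's radial extent is compressed to
`wall_offset − 2 × lattice_thickness` and centred at the `height_offset`
fraction of the wall (default 0.5, i.e. mid-wall), which guarantees the
lattice lies strictly between the inner and outer surfaces. Mapping every
mesh vertex (rather than rigidly placing cells) lets struts bend with the
surface; for cells much smaller than the tube radius the metric distortion
is second-order.

## Tensile analysis

Engineering stress is `F/A0` with `A0` from the specimen width times the
mean of five thickness measurements; engineering strain is clamp
displacement over gauge length. Records begin with a 0.02 MPa preload and
three 0–1 N conditioning cycles; the analysed segment is the final monotone
loading ramp (detected as everything after the last displacement decrease),
with strain re-referenced to the ramp start.

The averaged-curve pipeline follows the order: linear interpolation of every
sample onto a common grid whose length is the median raw length (the common
axis is the normalised test-duration fraction) → decimation by 10 (every
tenth sample of the 100 Hz record) → zero-phase 2nd-order Butterworth
low-pass at 0.1 Hz, interpreted at the *decimated* 10 Hz rate (at the raw
rate the cutoff would sit at 0.1 % of Nyquist and flatten the curve shape) →
averaging of stress and strain across samples → central differences of both
channels → the same filter re-applied to both derivatives →
`E_inc = σ̇/ε̇`, restricted to 15–90 % of the test duration. Filtering is
zero-phase (forward–backward), so curves are not phase-lagged before
averaging; whether filtering happens before or after averaging is exposed as
an option (default: before). On a noiseless linear record the pipeline is
exact — the odd-extension padding of the zero-phase filter preserves linear
signals — and on the exponential tissue model it tracks the analytic
derivative to ~1 % inside the window.

Max stress and the strain at max stress are taken per sample from the raw
(trimmed, unfiltered) curves, ties resolving to the first peak; batch
statistics are the sample mean, the ddof = 1 standard deviation and their
ratio (CoV). Comparisons use Welch's unequal-variance *t*-test from summary
moments, one-sided at α = 0.05; the relation classifier runs both one-sided
tests and reports "equal" when neither rejects. Literature entries rarely
publish sample sizes, so comparisons assume n = 6 (matching the printed
batches) unless overridden — this choice changes equality calls and is
recorded in every report.

## Synthetic records

Three closed-form engineering stress–strain laws emulate the material
classes seen in such experiments:

* polymer (strain-softening): `σ = aε/(1+bε)`, tangent modulus
  `a/(1+bε)²` strictly decreasing — defaults a = 1.2 MPa, b = 1.5;
* tissue (strain-stiffening): `σ = A(e^{Bε} − 1)`, a one-dimensional proxy
  for the exponential collagen response of arterial wall models — defaults
  A = 0.05 MPa, B = 3;
* composite rupture: rule-of-mixtures blend of a matrix and a lattice model
  (lattice fraction 0.15) whose total stress is scaled down by a smoothstep
  drop (40 %) over the 70–80 % strain band as the matrix ruptures, with
  final rupture at 105 % strain. The defaults approximate a published
  chain-reinforced sample that peaked near 0.9 MPa at 70 % strain.

Records are sampled at 100 Hz during a 10 mm/min constant-rate ramp on a
10 mm gauge (so 100 % strain takes 60 s / 6000 samples), preceded by three
triangular conditioning cycles up to the 1 N displacement found by root
solving. Measurement noise is additive Gaussian on the load channel
(default SD 0.005 N — no instrument noise figure is published, so this is a
package default, configurable); inter-sample variability multiplies the
stress-scale parameters by Normal(1, CoV) factors (default CoV 0.05, the
order of the published printed-batch CoVs). All randomness derives from one
integer seed through `numpy.random.SeedSequence` spawning, so batches are
reproducible and sub-streams independent.

What the generator does *not* emulate: viscoelasticity and rate dependence,
hysteresis in the conditioning cycles (conditioning displacement is replayed
through the same elastic law), anisotropy, slippage in the clamps, and true
(as opposed to engineering) stress–strain. Passing tests therefore validate
the signal-processing and statistics chain under the stated mechanical
models, not the constitutive behaviour of real printed polymers.

## Numerical choices and degenerate inputs

Vertices are merged at 1e-6 mm; meshes with negative signed volume are
reoriented at construction. Strain-rate zeros in the modulus ratio are
masked with a warning rather than propagated as infinities. Records whose
time base deviates from 100 Hz are linearly resampled with a warning; a
missing geometry header is a hard error. Zero-variance summary pairs fall
back to a degenerate t (0 or ±∞). Curves shorter than 10 samples are
rejected from alignment. Empty lattices embed to the bare slab and report a
volume fraction of 0.

## Known limitations

* The chain/knitted/origami constructions are calibrated interpretations of
  under-specified published geometry; printed fractions could differ by a
  percentage point or two depending on the authoring CAD's sweep and offset
  conventions.
* The conformal tessellation targets smooth, moderately curved tubes; it
  rejects centerlines whose curvature radius is below the outer wall radius
  instead of attempting self-intersection repair.
* The analysis assumes displacement-controlled tests with a clean final
  ramp; load-controlled or cyclic protocols are out of scope.
* Statistical comparisons from summary moments inherit the assumed-n
  convention for literature entries; conclusions near the 5 % threshold can
  flip with that choice.
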