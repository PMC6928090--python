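# Methods

## Scope and model

`memdeform` post-processes trajectories of a planar lipid bilayer
under shear flow, optionally with embedded transmembrane proteins. It
does not run or emulate the molecular dynamics itself: its inputs are
a topology (atoms with element, mass and a role label), a coordinate
trajectory sampled at a uniform interval (0.1 ns by default), and
optional per-atom force/velocity tables. Roles partition the atoms
into `upper_head_heavy`, `lower_head_heavy`, `protein` and `other`;
the two head-heavy roles are restricted to C, N and P, the heavy
atoms of phosphatidylcholine head groups, whose z-positions define
the two membrane surfaces. Leaflet membership is taken from the role
labels supplied by the user's pattern rules, never inferred
geometrically (a mid-plane classifier exists as an explicit
suggestion helper only): for a membrane built by construction, the
labels are exact, and silent geometric inference would misassign
atoms during large excursions.

Units are fixed package-wide: Å, ns, Å/ns, pN, amu. A force table in
kcal·mol⁻¹·Å⁻¹ must be declared as such (`unit="kcal/mol/A"`, factor
69.4786 pN); the reader never guesses.

The box is a rectangle (Lx, Ly), periodic in x and y and open in z.
The physical membrane unit is hexagonal; the rectangle encloses it
and the cells outside the hexagon are simply never occupied, which
the validity mask records.

## Height maps

The rectangle (320 × 360 Å² by default) is meshed into square cells
(5 Å spacing → 64 × 72 = 4608 cells). Cell membership uses the
half-open convention `[x0+iΔ, x0+(i+1)Δ)` on wrapped coordinates; an
atom exactly on the far box edge wraps to the origin side, giving a
deterministic, gap-free tiling. A cell's height is the arithmetic
mean z of the head heavy atoms inside it. Cells with no atoms are
*invalid* and are represented by an explicit boolean mask with NaN in
the height array — never a numeric sentinel, which invites silent
arithmetic on junk. The global mean height `h̄ = Σh_i/n` runs over
valid cells only. Local thickness is the cellwise difference of the
upper and lower maps where both are valid; the frame-average
thickness is the mean over those jointly valid cells.

## Deformation statistics

Per frame, the `top` value is the mean of the k largest valid
heights, `bottom` the mean of the k smallest, deformation =
top − bottom; k defaults to 5 and is stored in each record so the
insensitivity of the statistic to k (checked over k ∈ {3, 5, 10} on
noisy synthetic surfaces) is a test, not an assumption. Skewness of
the valid-height distribution uses the adjusted Fisher–Pearson
(bias-corrected) estimator; its OLS slope against time is the
stationarity diagnostic — a slope within 2 standard errors of zero
means asymmetry does not accumulate over the run.

Hills are cells with `h_i > h̄`, valleys `h_i < h̄`; the tie `h_i = h̄`
falls to the valley branch in the label map but is tallied in a
separate `zero_deviation` counter rather than in the category counts,
because the weak-deformation category is the open interval (0, 4) Å
and silently folding measure-zero ties into it would misstate the
partition. Categories by `|h_i − h̄|`: I ≥ 8 Å, II [4, 8) Å,
III (0, 4) Å. Cumulative category distributions pool cell-frame
observations by default (each side normalized to 1, zero-deviation
cells excluded); a per-frame-averaged variant is provided since the
two differ when the valid-cell count varies between frames.

Mean ± SE summaries treat frames as independent (SE = s/√n). Membrane
surface series are temporally autocorrelated, so this SE can be
optimistic; `standard_error(values, block_size=...)` provides
block-averaged SEs for users who want to discount the correlation.

## Kinematics

The strain rate is the single shear component
`ε̇_zx = v̄_x,rel / d`. Leaflet velocities default to finite
differences of consecutive frames, `(x_t − x_{t−dt})/dt`, with
minimum-image unwrapping in the periodic plane — valid as long as no
atom drifts more than Lx/2 per sampling interval, which at 0.1 ns
would require an implausible 1600 Å/ns. Files carrying explicit
velocities can use them directly. `d` is either the fixed
representative bilayer thickness (42 Å default) or the frame's
average local thickness; with flat leaflets the two modes agree
exactly, which is a test. The net driving force is the per-frame mean
x-force over the upper leaflet's head heavy atoms, then a time mean —
the simplest aggregation consistent with "mean force on the upper
surface"; absent per-atom forces are an error, not a zero. The
z-velocity diagnostic reports both the signed per-frame mean and the
mean absolute value, since either reading of an "average z-velocity"
can be wanted.

## Proximity

The protein rectangle is either the tight per-frame x,y bounding box
of the protein atoms (default, since the protein drifts under flow)
or a fixed rectangle — 30 × 40 Å² centred on the protein's mean
position, or four explicit coordinates used verbatim. The ring is
built on whole grid cells: the rectangle is snapped outward to cell
boundaries, expanded by `margin_cells` (default 5) cells per side
with periodic index wrapping, and the snapped-rectangle cells are
removed. The local height averages the raw z of head heavy atoms in
ring cells (atom weighting; cell weighting is an option), while the
global height averages valid cell means — the asymmetry is kept
deliberately, as the two estimators answer different questions (local
crowding vs surface shape). Protein elevation is the mass-weighted
COM z.

Decompositions: protein lift = local − global height; per-surface
flow contribution = (deformation_flow − deformation_stationary)/2,
halved because the deformation statistic spans both tails of one
surface while the flow acts on each surface once. The raw difference
is simply twice the returned value.

## Case comparison

One-way fixed-effects ANOVA (scipy `f_oneway`) across per-frame
series, reported omnibus over all cases and pairwise against a base
case (both, since either convention is common), with stars at
p < 0.001 and p < 0.01. Frames are again treated as independent; the
block-averaging caveat above applies.

## Synthetic generator

The generator provides statistical structure for testing, not
physics: all dynamics are kinematic prescriptions whose parameters
are recorded as ground truth, so every downstream statistic has an
independent oracle.

Geometry: a regular hexagon (circumcircle diameter 179 Å, flat sides
parallel to the flow axis, vertices on the x-axis through the centre)
centred in the 320 × 360 Å² rectangle. Head atoms sit on a jittered
square lattice at `head_density` per leaflet, clipped to the hexagon;
each site is one pseudo-atom of phosphorus by default (the analysis
only consumes positions and roles), with a 3-atom C/N/P head variant.
The default density, 0.12 atoms/Å², corresponds to ~8 C/N/P head
heavy atoms per lipid at ~65 Å² per POPC — about 3 atoms per 5 × 5 Å²
cell, so nearly all hexagon-interior cells are valid.

Surfaces: upper leaflet `z = +d0/2 + u(x,y,t) + bump + noise`, lower
`z = −d0/2 + u(x,y,t) + noise`, with d0 = 42 Å. `u` is a sum of
travelling sinusoidal modes; the default is one mode of amplitude
3 Å, wavelength 80 Å (commensurate with the box) and angular speed
2 rad/ns, with 0.5 Å Gaussian z-noise per atom per frame — height
fluctuations of a few Å, matching the scale at which the category
thresholds (4/8 Å) are meaningful. Noise enters z only; in-plane
positions carry static lattice jitter, so finite-difference
x-velocities of the drifting leaflets are exact. Default drifts are
4.2 Å/ns (upper) and 0 (lower), chosen so the recovered strain rate
at d = 42 Å is the round 0.1 ns⁻¹. The protein is a cylinder (radius
12 Å, height 60 Å, 400 equal-mass atoms) whose COM z follows a
prescribed trajectory, with an upper-leaflet Gaussian lift bump
`L·exp(−r²/2w²)` (defaults L = 2.5 Å — the magnitude of the observed
protein lift — and w = 15 Å). Per-atom x-forces on upper head atoms
are i.i.d. Normal(0.5, 0.2) pN per frame. A given seed makes the
whole output bit-reproducible.

What the generator does *not* emulate: molecular detail (water, ions,
glycan chains), force-field physics, thermal roughness spectra,
area/thickness fluctuations coupled to composition, or any feedback
between flow and surface shape. Passing tests therefore demonstrate
that the *analysis* is correct on surfaces of known geometry and
kinematics — not that the MD observables themselves are reproduced.

## Numerical choices and problem sizes

Tolerances in tests reflect each check's error budget: exact
assertions where the arithmetic is exact (sort-based top/bottom
oracle, enumeration of category tallies, flat-bilayer thickness),
relative bounds where cell-averaging attenuates a smooth surface
(deformation recovery within 5% of the true range 2A; cell means vs
the generating surface within the curvature bound `A(πΔ/λ)²` on cells
fully inside the hexagon), CLT/Monte-Carlo bounds for stochastic
quantities (net force within 3σ/√n per frame; the Category-I fraction
of i.i.d. normal heights within 4 Monte-Carlo SDs of `2Φ(−8/σ)`).
Degenerate inputs error loudly: no valid cells, fewer valid cells
than k, zero-frame trajectories, non-positive thickness, empty rings,
missing forces.

Test and acceptance runs use small problem sizes — tens of frames,
10³–10⁵ atoms — which complete in seconds while leaving the
statistical bounds comfortably satisfied; the pipeline itself streams
frame by frame and scales linearly in atoms × frames.

## Known limitations

- No interpolation of invalid cells and no undulation-spectrum
  analysis; the height map is used as-is.
- Rectangular-periodic boxes only; no triclinic cells, no z-imaging.
- SEs and ANOVA treat frames as independent; block averaging is
  offered but not default, mirroring common practice.
- The net-force aggregation order (per-frame atom mean, then time
  mean) is the simplest consistent reading of a mean surface force;
  alternative windowed definitions are not implemented.
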