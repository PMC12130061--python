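# Methods

## The analysis model

The pipeline treats a vessel as a space curve C(s) (the centerline,
parameterized by arc length s in mm) with a lumen radius profile R(s)
(the maximum-inscribed-sphere radius, MISR). All geometry is in mm,
velocities in m/s, flow rates in ml/s; the three meet only in
`synthetic.mean_axial_velocity`, where the unit factors cancel exactly
(1 ml/s over mm² gives m/s).

**Frenet frames.** Derivatives C′, C″, C‴ are nested second-order
finite differences on the (approximately) uniformly resampled curve,
taken against the stored abscissa so a shorter final interval is
handled correctly. Curvature is κ = |C′×C″|/|C′|³ and torsion
τ = (C′×C″)·C‴/|C′×C″|². The normal is the unit component of C″
orthogonal to the tangent, which enforces frame orthogonality to
machine precision rather than relying on |C′| being exactly constant.
On the helix fixture (a=3, b=4 mm, 0.15 mm spacing) the interior errors
are 2·10⁻⁴ (κ) and 4·10⁻⁵ (τ) relative; halving the spacing reduces
the κ error at second order.

*Validity mask.* Torsion and the normal/binormal are undefined where
the curve is locally straight (|C′×C″| < 10⁻⁸ 1/mm). In addition the
outermost **four** points at each end are masked: the nested third
derivative inherits one-sided edge errors three points deep, and
torsion there can be off by tens of percent. Downstream stages skip
masked points; they never propagate NaN.

**Smoothing** is explicit iterative midpoint relaxation
(p_i ← p_i + f·((p_{i−1}+p_{i+1})/2 − p_i), endpoints fixed), with the
clinical-resolution defaults f = 1.0 and 75 iterations at 0.15 mm
spacing. It is contractive for interior points, so total length never
grows.

**Decomposition.** With the slice frame (t, n, b) at centerline point
p, each sampled velocity splits into axial, radial and circumferential
parts (README formulas). The split is orthogonal by construction;
samples at the slice center (|r−p| < 10⁻⁹ mm) have no radial direction
and are excluded from in-plane statistics.

**ROI.** The near-wall band keeps normalized radii ρ ≥ √(1−w) where a
unit parabolic profile 1−ρ² falls below the fraction w of its peak
(w = 0.5 → ρ ≥ √0.5 ≈ 0.7071). The A-side is a 150° sector centered
on the aneurysm's in-plane direction; the O-side is the same width
diametrically opposite — the width of the opposing sector is a package
choice (symmetry). Side means are means of sample-wise magnitudes, not
magnitudes of mean vectors. Orientation classes use the in-plane angle
to the Frenet normal: "out" ≤ 30°, "top" within 30° of 90°, otherwise
"tilted"; the bands are configurable because only the class names, not
their boundaries, are standard.

**Landmarking.** A bend is a κ peak flanked by the nearest proximal and
distal |τ| peaks; shared τ peaks become shared borders, and a missing
flanking peak falls back to the domain endpoint (flagged). Peaks are
strict local maxima after a light moving-average pre-smooth, with
prominence ≥ 0.05 of the signal range and ≥ 3 mm separation. The
prominence default is deliberately low: cohort vessels mix gentle and
sharp bends (peak-curvature ratios up to ~8), and a higher threshold
starts dropping the gentle ones. |τ| makes the frame handedness
convention irrelevant.

**Cohort statistics.** Per-bend sectional means are unweighted means
over member slices (peak κ is the max). Case-relative normalization
divides each velocity quantity by its maximum over the case's
(bend, side) sectional means — the "max over bend means" reading; a
`velocity_max` override lets callers normalize by per-slice maxima
instead. Curvature quantities normalize by the maximum κ along the
whole analyzed centerline. Velocity comparisons use the A-side sector
only (the side hosting the aneurysm), A-bend vs O-bend, with the Welch
t-test (α = 0.05, two-sided); p-values are reported raw, with an
optional Holm-adjusted column off by default. Box summaries use the
1.5·IQR whisker rule.

## The synthetic generator

Real inputs would be segmented ICA lumens and time-averaged CFD
velocity fields; neither is reproducible at a desk, so the generator
builds cases with the statistical structure the analysis assumes.

*Geometry.* Multi-bend centerlines are defined by smooth profiles:
κ(s) is a small positive baseline (0.02 1/mm) plus one cos² bump per
bend, τ(s) one cos² bump per inter-bend transition scaled to integrate
to the twist angle, and the curve is obtained by integrating the
Frenet–Serret equations (RK4 with per-step re-orthonormalization).
The positive curvature baseline exists because Frenet torsion is
undefined on exactly straight segments: a piecewise-arc construction
with straight transitions would make the very torsion peaks the
landmarking needs unmeasurable. The exit transition repeats the last
bend's twist so n bends with nonzero twists produce n+1 torsion peaks
interleaving the n curvature peaks; a curve with all twists zero stays
exactly planar.

*Flow.* At each cross-section the axial profile is parabolic,
2U(1−ρ²) along the tangent with U = Q/(πR²), and the secondary flow
derives from the stream function ψ = A ρ(1−ρ²)² sinθ (θ from the
Frenet normal): v_ρ = A(1−ρ²)² cosθ, v_θ = −A(1−ρ²)(1−5ρ²) sinθ.
This is the simplest symmetric vortex pair that satisfies no-slip at
the wall and regularity at the axis, mimicking Dean flow in a curved
pipe. The amplitude is A = c·κ·R·U — the dimensionless curvature
ratio κR times the mean speed, with coupling constant c = 1 — so the
secondary flow strength tracks local curvature, which is precisely the
property the cohort analysis is meant to detect. Q comes from the
cycle-averaged inflow law Q = 48.21 A_in^1.84/T at the case's inlet
area and a 0.8 s cardiac period. The field is exported as a scattered
point cloud (not a mesh) so the analysis exercises the same
interpolation path a CFD export would.

*Cohort defaults* (`synthetic.POPULATION_DEFAULTS`): 3 bends per case;
per-bend peak curvature ~ N(0.20, 0.10²) 1/mm floored at 0.05; the
designated aneurysmal bend shifted by +0.10 1/mm; twists 15–40° with
random sign; bend arcs ~15 mm, transitions ~8 mm, ±10 % length jitter;
lumen radius ~ N(2.3, 0.15²) mm with a ±18 % sinusoidal taper;
per-bend lognormal secondary-amplitude jitter (sd 0.30 in log space)
emulating upstream-history effects; additive velocity noise
σ = 0.002 m/s emulating export/interpolation-level perturbation of an
otherwise smooth time-averaged field; aneurysm neck ±2 mm around the
aneurysmal bend's curvature peak; orientation classes assigned
uniformly (their real distribution is unknown). These values were
calibrated once so the normalized cohort summaries (n_cir A-group
≈ 0.85 ± 0.21 vs O-group ≈ 0.66 ± 0.27) sit close to published
patient-cohort values, and are not per-experiment knobs.

*What the generator does not emulate:* non-circular lumens, bifurcation
outflow, pulsatility (a single time-averaged field per case), wall
compliance, secondary-flow structures beyond a single symmetric vortex
pair, and imaging/segmentation error. Passing tests therefore show the
pipeline recovers curvature-coupled secondary flow under these idealized
conditions; they do not validate the hemodynamic claim on patients.

## Numerical choices

- Resampling interpolates linearly along the input polyline, preserves
  both endpoints (the final interval may be shorter; flagged), and
  recomputes the abscissa from chord lengths.
- IDW interpolation uses k = 4 nearest field points with power 2, an
  exact-value short-circuit at coincident nodes, and a mask cutoff of
  1.5× the mean field spacing. The neighbor set is extended to all
  points tied (to 10⁻⁹ relative) with the k-th distance, which keeps
  the interpolant exactly equivariant under rigid motions of cloud and
  samples despite the symmetric tie patterns of regular clouds.
- Analysis problem sizes for cohort studies: 0.25 mm centerline
  spacing, every 4th point sliced, 8×24 polar samples per slice, field
  clouds sampled on 24 angular rays at every 2nd centerline point.
  These give per-case run times well under a second while keeping
  quadrature error far below the biological variability being studied.
- Ties: a neck midpoint exactly on a bend border goes to the distal
  bend; with a 180° sector the O-side uses a strict inequality so the
  two sectors partition the band.
- Degenerate inputs: constant peak-detection signals yield no peaks;
  zero-variance Welch groups with equal means return p = 1, with
  unequal means they are an error; an all-zero velocity field fails
  normalization explicitly.

## Known limitations

- The Frenet normal flips across inflection regions; the baseline
  curvature in the generator avoids true inflections, but real
  centerlines with near-straight segments will have masked stretches
  and the orientation classification is undefined there.
- MISR from surface point sets is a nearest-point distance query; for
  coarsely sampled walls it underestimates the radius by up to the
  wall sampling distance.
- The per-ray wall-distance march for point-cloud lumens
  (`sections.wall_from_field`) assumes the cloud fills the lumen with
  roughly uniform support; thin boundary layers of missing points bias
  the wall inward.
- Welch group sizes follow one A-bend and ~two O-bends per case;
  cohorts whose landmarking yields different bend counts will change
  group sizes, which is reported in the output table.
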