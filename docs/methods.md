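# Methods

This note documents the measurement model implemented by `torsofit`, the
numerical choices behind it, what the synthetic phantoms do and do not
emulate, and the package's known limitations.

## Input model

All computations operate on watertight triangulated surfaces in
millimetres, in a patient-anchored frame: +x patient left, +y anterior,
+z superior. Reading a mesh merges vertices closer than 1e-6 mm and drops
faces with area below 1e-12 mm²; a cleaning report (merge and drop counts)
is attached to the mesh. No unit autodetection is attempted — CAD exports
with other units must be scaled by the caller, because silent unit guessing
is a classic source of wrong volumes.

## Torso asymmetry index

Pipeline: mid-sagittal plane → mirror → rigid ICP of the mirror onto the
original → trim both to the common z-interval → volume between the two
solids ÷ volume of the trimmed original × 100.

**Mid-sagittal plane.** In interactive CAD workflows the mirror plane is
placed by hand. For reproducibility the package estimates it from the
principal axes of the vertex cloud: the dominant principal direction is
taken as longitudinal, and among the remaining two the direction most
aligned with ±x (re-signed to +x) is the plane normal; the plane passes
through the vertex centroid. An explicit plane override is accepted
everywhere for meshes whose pose violates the frame convention.
Near-isotropic vertex clouds (e.g. a sphere), where the lateral axes are
not identifiable, raise an error rather than returning an arbitrary plane.

**ICP.** Point-to-point rigid ICP: `sample_size` area-weighted surface
samples are drawn from the mirrored mesh with a seeded generator, matched
to their *exact* nearest points on the target surface, and the
least-squares rigid update is the SVD (Kabsch) solution; iteration stops
when the RMS residual changes by less than `convergence_tol` or after
`max_iterations`. Five consecutive non-decreasing residuals end the loop
with a warning rather than an error. Defaults: 5000 samples, tolerance
1e-4 mm, 100 iterations, explicit seed. The default tolerance is tuned for
the mirror-registration use, where the start point is already close; for
transform-recovery experiments across larger displacements a tighter
tolerance (1e-6 mm, 300 iterations) is used, since on smooth, nearly
axisymmetric shapes the residual decays slowly along the azimuthal
near-symmetry direction.

**Trimming.** Both solids are sliced to the intersection of their z-ranges
with planar caps, so both are watertight for the volume stage. The
denominator volume is the *trimmed* original, consistent with trimming
before the volume measurement. Slicing requires at least 10% overlap of
the larger z-extent.

**Volume between the surfaces.** "The volume enclosed between" two nearly
coincident closed surfaces is operationalised as the volume of the Boolean
symmetric difference of the two solids: it is sign-unambiguous, symmetric
in its arguments, and reduces to the intuitive inter-surface shell for
non-intersecting offsets. It is computed by occupancy voxelization on a
shared grid (default pitch 2 mm): a vertical ray is cast through each
(x, y) cell-column centre, triangle crossings are accumulated, and cells
are filled by crossing parity; a cell counts when exactly one solid
contains its centre. The estimate converges to the exact Boolean volume as
the pitch shrinks; on analytic fixtures (offset cubes, nested spheres) the
error at 1 mm pitch is below 2% (0.25% for the spheres). Exact mesh
Booleans were rejected because near-coincident surfaces — exactly the
regime of a torso and its registered mirror — are their worst case.
The ray grid is offset from the cell lattice by a sub-micrometre irrational
fraction of the pitch so that rays cannot hit projected triangle edges of
axis-aligned geometry, which would double-count crossings.

## Signed displacement field and segments

For every torso vertex the exact closest point on the brace surface is
found (point-to-triangle, not point-to-vertex: surface distance is
mesh-resolution independent and strictly smaller or equal). The sign is
decided by a generalized winding number test of that closest point against
the torso solid: inside → positive (pressure zone), outside → negative
(expansion zone), within 1e-6 mm of the torso surface → zero. No
registration is performed between torso and brace — the models are assumed
already aligned, as they are by the brace-design workflow; an upstream ICP
call can be made explicitly if needed.

Exact nearest-point queries use a median-split AABB tree with
branch-and-bound traversal (numba-compiled, with a pure-numpy fallback);
results equal a brute-force scan over all triangles to 1e-9. The winding
number is the summed van Oosterom–Strackee solid angle over all faces; the
0.5 threshold makes the test robust to small self-intersections, unlike
ray parity.

The 12 segments split the torso z-range into equal-height thirds
(upper/mid/lower), anterior from posterior by the coronal midplane through
the vertex centroid (+y normal), and patient-left from right by the
sagittal midplane (+x normal through the centroid, or a supplied plane —
e.g. the asymmetry module's estimate — for consistency across analyses).
Boundaries are half-open: on-plane vertices go to the lower / posterior /
right side. "Equally divided" is read as equal z-height, not equal vertex
count or volume. Per segment, the peak positive value is the maximum over
positive field values (0 if none) and the peak negative the minimum over
negative values (0 if none); empty segments are flagged.

## Cohort statistics

In-brace correction is `100 · (CA_pre − CA_in-brace) / CA_pre`; the
percentage may be negative (in-brace worsening). Group summaries are
sample means and n−1 standard deviations of the per-patient percentages
(not ratios of means). Correlations are Spearman's ρ with average-rank tie
handling (scipy implementation; verified in tests against the exhaustive
rank formula over all 720 permutations at n = 6). Strength bins follow the
conventional ranges; because the printed ranges leave gaps (0.695, 0.895),
the bins are half-open on |ρ|: [0.90, 1.00] very strong, [0.70, 0.90)
strong, [0.50, 0.70) moderate, (0.25, 0.50) weak, [0, 0.25] little if any;
the sign is reported by the ρ value itself. Constant feature vectors yield
an "undefined" row rather than an error. No p-values or multiple-testing
correction are computed: the tables report ρ and its strength category
only. Correlation tables require at least 3 records per group and list the
24 segment-peak features in the fixed ALU…PRL order, positives first.

## Synthetic phantoms and cohorts

**Torso.** A generalized cylinder: elliptical cross-sections (default
half-axes 140 × 110 mm) swept over a 450 mm height with a mild waist
taper, laterally offset centreline (sinusoidal bump peaking at `apex_z`,
emulating curve convexity) and an azimuthally Gaussian rib hump. With zero
offset and hump the phantom is *exactly* mirror-symmetric about x = 0 by
construction (even azimuthal sampling), which provides the null case for
the asymmetry index. The mesh is a closed ring lattice with cap fans,
watertight and outward-oriented; for the untapered case the enclosed
volume matches π·a_x·a_y·h to better than 1%. Default resolution 48 × 48
(rings × points per ring).

**Brace.** Derived from a torso by displacing vertices along inward vertex
normals under summed Gaussian pad profiles in (z, arc-length) coordinates:
positive depth presses into the torso (pressure), negative depth relieves
outward (expansion). Pad centres snap to the torso vertex nearest the
nominal segment centre, so the planted peak depth is realised exactly at a
sample point; measured peaks recover planted depths within 5% at the
default pad width (45 mm Gaussian σ). Depths whose summed profile exceeds
half the smallest cross-section radius are rejected as self-intersection
risks. Topology is unchanged, so the brace inherits watertightness.

**Cohort.** Pre-brace Cobb angles are drawn per curve type from normal
distributions matching the study population (AP: 38.4 ± 14.8° for main
thoracic, 30.5 ± 5.8° for thoracolumbar/lumbar; lateral: 21.2 ± 15.0° and
48.3 ± 11.9°), truncated at the 20° inclusion threshold (5° lateral).
Torso shape parameters vary per patient; each brace carries one pressure
pad on the curve convexity (PRU for Lenke 1, ARM for Lenke 5; depth
U(4, 10) mm) and one relief pad in PLM (depth −U(2, 10) mm). IBC is
generated *top-down* from features measured by the real geometry pipeline:
`IBC% = intercept + Σ coef·feature + ε`, default a single coefficient of
−2.0 on the PLM peak-negative displacement with intercept 25 and Gaussian
noise. The noise SD default of 3.0 was calibrated once by large-sample
simulation (4×10⁵ draws) so the population Spearman correlation between
the PLM feature and IBC is ≈ −0.85, the magnitude of the strongest
association the pipeline is meant to detect; at n = 50 the sample ρ falls
in [−0.95, −0.70] in well over 80% of seeds. The in-brace Cobb angle is
back-computed from the generated IBC. All randomness flows from one seed
through a `SeedSequence` spawn per patient; no global random state is
touched. This generator validates the *statistical* pipeline; it makes no
claim of biomechanical realism (IBC is not derived from contact forces).

**What passing tests do and do not show.** The phantoms are smooth and
star-shaped with analytic ground truth; they exercise every geometric
operator but do not contain scanner noise, holes, self-intersections,
anatomical detail (arms, pelvis) or non-rigid posture differences. Results
on real scans depend additionally on scan quality and on the manual
alignment of torso and brace, which the pipeline deliberately does not
correct.

## Problem sizes and determinism

Default working resolutions: 48 × 48 phantom (≈ 2.3k vertices) for
single-shape analyses, 32 × 32 for full simulated cohorts, 24 × 24 (the
generator minimum) for the 100-seed Monte-Carlo recovery experiment, and
142 × 142 (≈ 20k vertices) for transform-recovery benchmarks; the voxel
pitch default is 2 mm (1 mm in the analytic volume oracles). These sizes
keep the whole validation battery at a few minutes on a single CPU while
leaving every tolerance comfortably met; all of them are parameters, not
constants. Fixed seeds give bit-identical ICP transforms, meshes, cohorts
and output tables; table files are written with fixed float formatting so
repeat runs are byte-identical.

## Limitations

- Caps for slab slicing are centroid fans over the cut boundary loops —
  exact for star-shaped cross-sections (all shapes this pipeline meets),
  wrong for cross-sections whose boundary is non-star-shaped.
- Mesh repair is limited to vertex welding and degenerate-face removal;
  open or self-intersecting scans must be repaired upstream.
- The displacement field lives on torso vertices (not resampled), so peak
  values inherit the torso mesh resolution; this mirrors the point-wise
  definition of the measurement but means very coarse meshes can miss
  narrow pads.
- The mid-sagittal plane estimator assumes the longitudinal axis dominates
  the vertex covariance and that the pose roughly follows the frame
  convention; unusual poses need the explicit plane override.
- Lateral-view effects are simulated as noise-only by default; the lateral
  correlation tables exist to exercise the table machinery, not to encode
  a lateral effect model.
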