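# Methods

This note documents the models, numerical choices and open design decisions
behind `ocuprost`, in the spirit of a package methods appendix.  It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Canonical frame and alignment

All geometry lives in an iris-plane frame: limbus centre at the origin, +x
nasal, +y superior, +z toward the cornea.  Alignment of a marked scan
translates by the negated marker centroid and applies the least-squares
linear map sending the centred markers (nasal, superior, inferior,
temporal) onto (+x, +y, −y, −x); because a least-squares matrix is not
generally orthogonal it is projected to the nearest proper rotation by SVD,
keeping the transform rigid.  Left-eye scans are mirrored across the y–z
plane with triangle winding flipped, so every shape fits a right socket.
Markers that do not span a plane raise `AlignmentDegenerateError`.

## Correspondence representation

A prosthesis surface intersects any line parallel to z at most twice, so it
is fully described by front (max-z) and back (min-z) orthographic depth
maps.  Landmarks are placed on 48 radial rays (7.5° steps) from the origin
to the silhouette of the projection, at fixed fractional distances; points
at equal fractions form rings, and sparse rings skip directions uniformly
to keep the density homogeneous.  The frozen version-1 scheme uses front
rings of (8, 12, 24, 48, 48, 48) points at fractions (0.12, 0.26, 0.42,
0.65, 0.85, 1.0) — the third ring marks the limbus — and back rings of
(8, 16, 48×13) points, each surface with a centre vertex, giving 189 + 649 =
838 landmarks.  A fixed triangulation (ring fans, merge-walk stitches and a
48-quad silhouette band) closes the surface with 1672 faces, 2508 edges and
Euler characteristic 2.  The exact fractions and skip pattern are a design
choice of this package, constrained by the published counts and the
limbus-on-ring-3 rule.

Depth maps for correspondence use 512×512 px over 32×32 mm (0.0625 mm/px),
bilinear sampling with nearest-valid fallback at silhouette boundaries, and
an error if a sample sits more than 2 px from any valid pixel.  The ring
scheme commutes with z-rotations that are multiples of every ring's angular
period (90° for this table); sub-multiples permute only the full 48-point
rings.

## Statistical shape model

PCA by SVD of the centred n×2514 matrix of flattened vertices.  No
Procrustes size normalisation: prosthesis size correlates with socket size
and is deliberately kept as shape variation.  Sample covariance uses the
n−1 divisor, so σᵢ is the sample standard deviation along mode i of the
flattened coordinates (per-vertex displacements are roughly σᵢ/√838); the
per-mode scaling makes shape-vector entries unitless standard deviations.
Mode signs are fixed deterministically (largest component positive); the
mode count k is the smallest with cumulative explained *variance* ≥ 98%.
Model quality is evaluated as mean (± sd) per-vertex Euclidean distances:
replication (training shapes through the model), generalization
(leave-one-out) and specificity (standard-normal samples against the
nearest training shape; 10 000 draws by default, seeded).  Reference values
reported for the original 173-prosthesis model (0.27 / 0.31 / 1.10 mm,
k = 17) are not reproducible here because that training stock is
proprietary; the synthetic family is 5-parametric, so its k is small.

## Conformers

A conformer is an SSM base shape with the anterior clamped to the window
plane z = −1.8 mm inside a 15 mm diameter and a conical frustum wall
(default slope 30° from the plane normal — the slope is geometry-only and
does not enter the extraction math, which uses thickness, offset and
refractive index).  The registry stores per-conformer shape vectors and
window geometry as JSON; window diameter is stored per conformer.

## Socket extraction

Slices are thresholded ((max(B, 25) − 25)/230), then denoised/downsampled
by median(5) → 2×2 median pool → median(3) → 2×2 median pool; trailing odd
rows/columns are dropped at each pool so 2145×1877 maps to exactly 536×469.
`B_Max` is plain 4×4 max pooling.  The edge image takes the second depth
derivative of `B_Max` masked to non-zero `B_Median`, with a separable
size-5 Sobel kernel (smoothing normalised to unit gain, derivative taps
[1, 0, −2, 0, 1]) and threshold −0.05.  Canonical voxel pitches are 16/536,
16/256 and 14/469 mm; the window thickness in voxels is τ = d/z-pitch.

Window tracing takes the first edge hit per column, initialises the
anterior mask below median + 0.75τ, and refines it 8 times against a
least-squares plane with the |D − P| < 0.5τ rule; the posterior surface
starts at D_A + 0.5τ with 4 refinements, then 3×3 median filtering and
binary opening clean the mask.  Socket tracing starts at D_B + 10 voxels
(the "+10" is taken as voxels), finds the brightest voxel z₁, the steepest
rise z₂ relative to the start, and the surface z₃ as the last zero-intensity
voxel before z₂; columns without signal or without a zero gap are dropped,
a 5×5 median comparison (0.5 mm) rejects outliers, and the process aborts
below 32 mm² of traced area.  The surface is placed at the leading boundary
of the first signal voxel, (z₃ + 1)·pitch.

Three corrections: (1) refraction through the tilted window — a thin-window
model correcting the in-plane beam displacement from the fitted anterior
plane normal, plus the empiric −0.35·d depth shift (in the canonical frame,
deeper is more negative z, so the shift is −0.35·d; for d = 1.5 mm that is
−0.525 mm, consistent with signals through the conformer appearing closer);
(2) an axial shift placing the anterior window plane at z = −offset, i.e.
the iris plane at zero; (3) a 6° rotation about the y axis for the gaze
angle (the rotation axis is not fixed by the published description; y —
toward nasal — is our documented choice).  The corrected point cloud is
averaged into the 256×256, 16×16 mm map `D_S` with mask `M_S`.  For
reduced-resolution synthetic volumes a proportionally coarser grid should
be requested, otherwise `D_S` is sparsely populated.

## Shape fitting

`Z_z` (back-surface depth) is realised as piecewise-linear interpolation of
the 649 back landmarks over their x-y projection (Delaunay-based), not
per-face rasterisation of the fixed face list: for a height-field back
surface the two differ only in the triangulation of near-planar quads, and
interpolation is much cheaper inside the optimiser loop.  Mask pixels the
projection misses are charged the worst in-mask squared residual, which
keeps the energy finite and penalises undershooting shapes.  Gradients are
forward finite differences (step 10⁻³) under L-BFGS-B; the energy is only
piecewise smooth, so a two-step-size difference consistency check stands in
for an analytic-gradient test.  Modes unlock three at a time (earlier modes
stay free, locked ones pinned at the target x_t), the box is ±3σ, and
saturation within 10⁻⁶ of the box edge triggers the extended fit with
bounded θ (±30°) and z (±2.5 mm) and penalty w_ext(θ² + z²), w_ext = 10⁴.

A consequence worth stating: for a pure axial misalignment m the stationary
point of the extended energy splits m between the modes, the residual and
z, because the quadratic penalty w_ext·z² is commensurate with the
normalised data term; z therefore recovers only a fraction of m (about half
of what the modes cannot absorb) rather than m itself.  The test suite
records this behaviour.

## Shape post-processing and reconstruction

Cornea renormalisation replaces the front rings up to the limbus with the
mean-shape cornea, scaled so the apex sits 2.5 mm above the iris plane and
the limbus diameter equals the requested iris diameter; rings 4 and 5
follow half and 0.15 of the limbus displacement as a smooth transition, and
the posterior surface is untouched bit for bit.  The 5% enlargement is a
radial scaling about the origin with a cosine blend from 1.0 at the
(maximal) limbus radius to 1.05 two millimetres further out on the front,
and 1.05 on the whole back.  The clear coat is 0.1–0.5 mm, thicker toward
the lid regions (large |y|) and the equatorial edge via smoothstep weights
— a documented stand-in for the hand-drawn lid map of the original
workflow; reconstructed shapes use a uniform 0.2 mm.  Smoothing runs two
rounds of Loop subdivision in which every stencil-displaced vertex that
moved inward along its outward normal is reflected across the tangent
plane, so the enclosed volume increases; face count quadruples per round.
Shapes with a bounding box strictly larger than 30×29×20 mm are rejected.
Reconstruction of an existing prosthesis uses the correspondence landmarks
directly (never the SSM round trip, which cannot represent out-of-span
detail).

## Colour

The characterization is A (3×3, RGB→XYZ, least squares) followed by
XYZ→CIELAB under D50/2° and a 3×7 root-polynomial correction on
(L*, a*, b*, √(L*a*), √(L*b*), √(a*b*), 1).  Because a* and b* are signed,
roots use sign(x)·√|x|; the reference patch configuration is 24 + 24 + 15
pairs.  The raw chain is demosaic (bilinear, GR Bayer; RGB input skips it),
strong non-local-means denoising (h = 15 on the 8-bit-equivalent scale),
dark subtraction, flat fielding, characterization, light denoising
(h = 1.5 in Lab).  Highlights are masked where the raw image saturates or
lightness deviates more than 10 L* from the 15×15 median, dilated twice
(3×3), and filled by Jacobi diffusion inpainting (300 iterations; the mask
radius after dilation is small, so convergence is ample).  Note the median
rule is insensitive to monotone edges but fires on small bright islands —
that is its purpose.

## Iris

Detection maximises the Gaussian-smoothed radial derivative of the circular
line integral of I_enh = C* − L* over an image pyramid (factors 8, 4, 2, 1,
each refining within ±4 px).  On I_enh the dark achromatic pupil is the
global maximum, so both boundaries are negative-derivative crossings.  The
pupil-plateau centroid anchors the centre — the circular operator drifts on
elliptical limbi — and the limbus circle is re-fitted about that anchor.
Elliptical refinement searches constant-area ellipses (axis ratios 1.0 to
0.85 in 0.01 steps, orientations every 5°) maximising the inside-minus-
outside contrast sampled at 0.96/1.04 of the contour; the narrow band makes
the true boundary the optimum.  Unwrapping samples bilinearly into a
4096×1024 angle-radius texture (row 0 at the limbus, pupil at the bottom);
eyelid-occluded sectors copy the nearest unoccluded column per row (a
stand-in for a full eyelid model).  Contrast enhancement stretches each row
about its mean by 1.5, restores the global mean lightness exactly, and sets
the bottom 16 rows black.  The iris mesh's pupil boundary is circularised
to its mean radius, the hole closed by a fan, UVs are (angle/2π, ρ/r_limbus),
and a black cylinder of pupil radius sits behind the pupil.

## Sclera

Segmentation median-blurs the image 20 times (alternating kernels 5 and 3),
seeds a watershed from the central cross-section (darkest pixel → pupil,
brightest on each side → sclera, derivative extrema → iris) plus image
corners for skin/aperture, and refines the sclera mask by L* ≥ 50, a
dilated iris mask, and a vein filter (C* > 8 and hue ≥ 345° or ≤ 60°).  The
palette is 9-colour k-means (k-means++ init, seeded) with lightness weights
wᵢ = (Lᵢ − Lmin)/(Lmax − Lmin) and the weighted mean as base colour; equal-
lightness palettes fall back to uniform weights.

Staining samples per-colour 3D gradient noise on a cylinder (seamless in
u; the v frequency is doubled so stains elongate circumferentially, as
conjunctival staining bands do), then thresholds the per-pixel maximum at
its 10% quantile — exactly 90% coverage — with a small per-colour bias
iteration equalising the painted areas within a few percent.  Phase/origin
offsets keep the u seam away from noise-lattice planes.

Veins grow over three layers from 10 seed positions along the fornix border
of the 2:1 domain; recipes (5 per layer, a versioned synthetic table)
control thickness, decay, depth, step, turn noise, limbus bias and
branching.  Growth stops at the limbus line, after a maximum step count, or
below a thickness floor; branches start at random nodes with 0.7× the local
thickness, the parent's depth and a random next-layer recipe.  `th` scales
all thicknesses and `br` all branching rates without touching the random
stream, so same-seed networks differ only in the scaled values.  Rendering
samples sliding-window quadratic B-splines (the four-knot construction is
read as overlapping 3-node windows), jitters the centreline sinusoidally,
stamps each sample's 21-value colour/alpha profile by distance to the
curve (profiles selected by weighted squared distance with 5× thickness
weight), and composites deep to shallow with a depth buffer, so shallower
veins win at crossings.  The 15 profiles are synthetic stand-ins (reddish
core, transparent flanks) for profiles sampled from photographs.

## Synthetic data

The prosthesis family is five-parametric (half-width, half-height, front
depth, back depth, posterior bump) over the published bounding-box envelope
(18.5×15.9×9.7 to 28.6×32.3×22.2 mm), built by deforming an icosphere, with
marker points placed analytically on the equatorial ring and arbitrary
rigid scanner poses.  Upper parts of that envelope genuinely exceed the
30×29×20 safety gate, as in the clinical workflow.  The OCT renderer
emulates exactly the acquisition effects the extraction corrects (gaze
rotation, depth bias, window refraction, one-sided interface reflections)
and returns the analytic truth surface; speckle is multiplicative gamma
noise plus salt dots — a pragmatic stand-in, not an OCT physics model.  The
eye-photo generator composites sclera, stains, veins, a streaked iris,
pupil, skin border and optional specular dots in CIELAB, applies a 2 px
Gaussian point-spread blur (real captures have no razor edges; several
detection rules depend on that), and maps to camera RGB through a known
XYZ mixing matrix.  Every generator is a pure function of its seed.

What passing tests show — and do not show.  The synthetic suite verifies
the algorithms against their own stated rules and analytic ground truths;
it cannot certify performance on clinical OCT speckle, real iris texture,
eyelash occlusion or camera noise, and the SSM metrics on the 5-parameter
family say nothing about the richness of real prosthesis shape variation.

## Problem sizes

Tests and the demonstration pipeline run at reduced sizes chosen to keep
the full suite in the minutes range: 16–50 training shapes at icosphere
subdivision 3, OCT volumes of 48×400×360 rendered pixels (tensor
100×48×90), photos of 384–512 px and textures of 256×128 to 1024×512.
Slice-level operations (threshold, cascade, t4-style width checks) run at
the canonical 2145×1877 resolution.  The canonical 256-slice geometry is
the module default throughout.
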