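# Methods

This note documents the quantification model implemented in
`spheromet`, its assumptions, parameter choices and known limitations.

## The measurement model

A spheroid image at endpoint contains three biologically distinct
populations: the compact **core** (the remains of the original
aggregate, possibly expanded, retracted, or hollowed by out-migration),
**edging** cells (migrating but still connected to the core — collective
invasion, capillary-like sprouts), and **detached** cells (single cells
or tube fragments shed into the matrix — individual invasion). All
measurements are defined on a binary cell mask and its decomposition
into these components.

### Frontier definition

The core/edging frontier is the *largest inscribed circle* of the
spheroid body. The body is the largest 8-connected component of the
mask with its internal holes filled — holes (background not 4-connected
to the image border) are cell-free gaps *inside* the aggregate and
belong to the body, while open bays connected to the exterior do not.
The circle is the global maximum of the Euclidean distance transform of
the body: its radius is the distance from the maximising pixel to the
nearest background pixel. Thin appendages cannot host the maximal
circle, so sprouts do not perturb the frontier. Ties between multiple
maxima are broken deterministically towards the centroid of the body.
Any other connected component of the mask is by construction detached;
a fragmented spheroid therefore contributes its largest fragment as the
body and the rest as detached material — the model assumes one spheroid
per image.

Component assignment: mask pixels whose centre lies inside the circle
are core; 8-connected components of the remainder sharing at least one
8-adjacency with a core pixel are edging; the rest detached. The three
masks partition the input exactly (asserted, not approximated), so
total area ≡ core + edging + detached in pixel counts.

### Density distribution

Around the centre of the *initial* spheroid (falling back to the final
core centre, with a warning, when no t = 0 image exists), concentric
digital circles of radius d_i = i·Δd are drawn. The digital circle at
d_i is the set of pixels whose centre lies within Δd/2 of the ideal
circle, i.e. the annulus [d_i − Δd/2, d_i + Δd/2); P_i is its pixel
count and the density of a component is N_i/P_i with N_i the component
pixels on the circle. Two properties follow by construction:

* densities lie in [0, 1], and disjoint components are additive at
  every radius (up to the empty-circle convention density = 0);
* consecutive circles tile the plane, so the curve integral
  Σ density_i · P_i · (pixel area) — the discrete counterpart of
  ∫ density · 2πd · dd — recovers a component's pixel area *exactly*
  within the covered radial range.

The second point is why the circle is defined as a half-*step* band
rather than a half-pixel-*diagonal* band: overlapping bands sample each
pixel in several circles, and on components of a few hundred pixels the
ring-versus-annulus sampling noise reached ±6% of the integrated area,
while the tiling definition makes the integration error identically
zero. The curves themselves are visually indistinguishable.

The default radial step is one pixel (converted to mm) — the finest
step the data support; the profile extends to the largest circle fully
contained in the image. Curves are emitted raw; smoothing is a
display-only option of the plotting helper.

Derived quantities: d₁ is the largest radius with nonzero total
density (equivalently the distance of the farthest cell pixel from the
profile centre); d₂ = d₁ − r_core, clipped at zero. By default r_core
is the *final* core radius — the conventional definition, which
deliberately ignores spheroid expansion; passing
`d2_reference="initial_core"` subtracts the t = 0 radius instead, which
is the appropriate choice when the core itself moves. Expansion is
r_f − r_i, the difference of the inscribed-circle radii of the endpoint
and t = 0 masks; it is negative for retraction.

### Segmentation

t = 0 images are bimodal and thresholded globally. Otsu's threshold is
computed on an explicit per-integer-level histogram for integer data,
which makes it bit-exact with an exhaustive search over all candidate
levels (the convention is `value > t` ⇒ foreground; ties resolve to the
lowest maximising level). A constant image raises a "no contrast"
error rather than producing an arbitrary mask.

Endpoint images are segmented as the union of two masks:

* the global-threshold mask, which captures the bright core (and, in
  clean images, everything else);
* the vesselness mask: the multiscale Frangi response (maximum over
  scales), thresholded at the 0.90 quantile of its *support*. The
  support is the upper class of an Otsu split of the positive response
  values. On a noise-free image the background response is exactly
  zero and the support is the literal nonzero set; on a noisy image
  every pixel has a small positive response, and the split separates
  the noise floor from structure so that the quantile is taken over
  structure responses only. A fixed quantile over *all* positive
  responses would otherwise admit a constant ~10% of the image
  regardless of content.

Finally 8-connected components smaller than `min_object_area`
(default 20 µm², below a single ~5 µm cell footprint) are removed.
Brightfield polarity is handled by negating intensities before any
thresholding (`invert=True`); no automatic polarity detection is
attempted, to keep behaviour deterministic.

Frangi parameters: scales {1, 2, 4, 8} px cover single cells to thick
capillary cords at ~1–2 µm/px; β = 0.5 (standard); the second-order
structureness sensitivity is half the maximum Hessian norm of the
image (scikit-image's adaptive default). As with any vesselness
pipeline, scales and the quantile should be adapted to magnification
and cell type; all are exposed in `SegmentationConfig`.

### 3D generalisation

Confocal stacks (one fluorescence channel) are processed slice-wise —
3×3 median filter then per-slice Otsu — and then in 3D: 26-connected
components spanning fewer than 3 slices are removed (at 3 µm slice
spacing such objects are smaller than a ~5 µm cell and are imaging
noise), and the volume is optionally downsampled by the logical OR over
non-overlapping 2×2×2 blocks (1024×1024×N → 512×512×N/2; odd trailing
planes are truncated; both calibrations double; no occupied block ever
empties, so no object is lost). A slice with no contrast binarises to
all-background rather than failing. Per-slice thresholding assumes
every slice contains some signal, which holds when the scan is cropped
to the z extent of the spheroid, as in acquisition; a signal-free
pure-noise slice would be mis-thresholded by any automatic method.

The core is an inscribed **ellipsoid**: orientation and axis ratios
from the eigendecomposition of the second-moment matrix of the filled
body in physical coordinates (semi-axes ∝ 2√λ, exact for a solid
ellipsoid), overall scale as the largest homothety contained in the
body — computed exactly as the minimum ellipsoidal coordinate over
background voxels. Because appendages skew raw moments (eight 6 µm
rods biased the semi-axes by ~9%), the moment fit is iterated three
times with voxels restricted to the neighbourhood u ≤ 1.3 of the
current ellipsoid, after which rod-laden phantoms recover their axes
to better than 1%. The frame does not bound the ellipsoid: a stack
cropped in z to the spheroid still recovers the full core.

Shell densities replace circles by the family of concentric ellipsoids
t·(a, b, c): shell i is the set of voxels with ellipsoidal coordinate
u ∈ [t_i, t_i + step), density is cell voxels over shell voxels per
component. The default shell step is 0.05 (≈ 4 µm at an 80 µm core).
An equivalent distance t·(abc)^{1/3} is reported for plotting against
2D profiles. Component volumes come from voxel counts times the
anisotropic voxel volume.

## Group statistics

Groups of spheroids are summarised as mean ± SEM (SEM is undefined and
reported as missing for n = 1). The percent change between a control
and a treated group is expressed relative to the **larger** of the two
group means: inhibition = 100·(c − t)/c when the treated mean is
smaller, stimulation = 100·(t − c)/t when it is larger. This is the
convention under which the published benchmark tables bundled in
`spheromet.reference_tables` reproduce their printed
inhibition/stimulation columns; of the 16 benchmark rows with a printed
percentage, 14 reproduce within ±1 point and two (one d₂ row and one
core-area row of the MMP2-inhibitor table) are internally inconsistent
in the source — the core-area row matches a baseline-relative
computation instead — and are knowingly left failing in the acceptance
tests rather than special-cased. Significance testing is out of scope.

## The phantom generator

All validation rests on synthetic phantoms because the assay has no
public reference images. A 2D phantom is a disk core (optionally with
internal circular gaps), radially oriented rectangular sprouts rooted
2 px inside the core boundary, and detached disks placed at sampled
distances with a guaranteed ≥ 2 px clearance from all attached
structure and from each other — so the attached/detached ground truth
is unambiguous under 8-connectivity; placement failure after bounded
retries raises an "overcrowded" error rather than silently degrading
the truth. The intensity image adds a linear illumination ramp and
Gaussian noise, and can be rendered in brightfield polarity. A single
seeded generator drives everything; equal specs give identical
phantoms.

Default geometry follows the assay at low magnification: 2 µm/px,
76 µm core radius, sprouts reaching ~0.28 mm from the centre, 12
detached cells of 4–8 µm radius within 0.12–0.32 mm — matching the
scale of reported measurements (initial radius ≈ 0.076 mm, d₁ ≈
0.33 mm). Noise experiments use σ = 5% of the foreground–background
contrast and a 10% illumination ramp. The 3D phantom renders an
axis-aligned ellipsoid core with radial rods and detached balls into
an anisotropic 24×256×256 grid (4 µm xy, 6 µm z), cropped in z to the
object, with exact voxel-count truth volumes.

What the phantoms do *not* emulate: textured cytoplasm, out-of-focus
blur, anastomosing sprout networks, intensity falloff with depth, and
touching detached cells. Passing the phantom suite therefore
demonstrates the geometry and measurement chain is correct — not that
segmentation parameters transfer to any particular microscope; those
must be adapted per application.

## Numerical conventions and degenerate inputs

* Distances between pixels are centre-to-centre; the inscribed-circle
  radius follows the distance-transform convention (distance to the
  nearest background pixel centre).
* The convex envelope is computed on pixel centres without half-pixel
  dilation, undercounting by at most ~perimeter/2 px²; masks with
  fewer than three non-collinear pixels have zero envelope.
* A radial step below one pixel, an empty mask, a constant image under
  Otsu, mismatched calibrations, and a core circle that misses the
  mask all raise explicit errors.
* Profile centres may be fractional; phantom cores are centred on an
  integer pixel so the rasterised truth circle and the recovered one
  coincide.
* All randomness is through `numpy.random.default_rng` with explicit
  seeds; there is no global random state.

## Problem sizes used in the test and acceptance runs

Phantom validation uses 256×256 images (25 phantoms per noise
condition, geometry randomised per phantom), 20 expansion pairs, and
one 60×256×256 confocal phantom stack; oracle comparisons use 200
random masks up to 64×64 (inscribed circle) and 100 random 8-bit
images (Otsu). These sizes keep a full verification run in tens of
seconds while exercising every code path at assay-realistic geometry.

## Known limitations

* One spheroid per image; no registration between t = 0 and endpoint
  images (they are assumed co-centred after centre detection).
* The density profile stops at the largest circle fitting inside the
  image; cells beyond that radius (outside the inscribed square) still
  count for d₁ but not for curve integration.
* The inscribed ellipsoid assumes a convex, roughly ellipsoidal core;
  strongly concave or dumbbell-shaped aggregates violate the model in
  2D and 3D alike.
* Per-slice automatic thresholding requires signal in every slice (see
  above).
* No machine-learning segmentation, colour deconvolution, nucleus
  counting, time-lapse tracking, or significance testing.
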