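# Methods

This note documents the models, conventions, parameter choices and
known limitations of cardioflow, in the spirit of a methods section: it
states what each stage assumes and computes, and what passing the test
suite does and does not demonstrate about real scanner data.

## Conventions

Indices are 0-based and a pixel's center sits at integer `(row, col)`;
continuous in-plane coordinates are in pixel units unless suffixed
`_mm`. Contour vertices are `(x, y)` with `x` along columns. Patient
coordinates follow the DICOM convention: position of voxel `(0, 0, 0)`
plus unit direction cosines along the row and column indices; the slice
normal is their cross product and slice centers are
`thickness + gap` apart. MR intensities are doubles scaled into [0, 1];
the stored integer bit depth is kept so the scaling is invertible
losslessly (12-bit by default). CT would be signed Hounsfield units; no
CT-specific processing is implemented beyond the container contract.

## Contour geometry

Contours are implicitly closed polygons at full double precision,
normalized to counter-clockwise orientation; self-intersecting rings
are rejected at construction. Areas use the shoelace formula with
anisotropic pixel scaling. Rasterization marks pixels whose **center**
lies inside the polygon, with centers exactly on an edge counted inside
(even-odd rule with inclusive boundary) — an arbitrary but deterministic
tie-break that makes axis-aligned test shapes exactly enumerable. The
same center-in-polygon rule is used everywhere a mask is needed (ROI
statistics, flow summation), so polygon areas and pixel counts diverge
only by the quantified sampling error.

## Sampling-error study

Measuring area by counting pixels mis-estimates the continuous polygon
area. For circular ROIs this is quantified by drawing circles with true
areas uniform on (0, 100] mm² and centers uniformly jittered within one
pixel cell, then comparing `h²·(pixel centers inside)` with the true
area at pixel sizes h = 1, 0.5 and 0.25 mm. The center-jitter +
uniform-area law is this package's choice of sampling scheme; the error
units are mm². Under it the error is unbiased and its SD scales as
h^1.5 (1.32, 0.46 and 0.165 mm² at the three default sizes with the
default n = 5000). Finer grids are rasterized directly rather than
emulated by image interpolation, because the geometric sampling error
is independent of image content.

## Phase-contrast flow

- **Velocity mapping** `v = (2p − 1)·VENC`: phase 0 is −VENC, 0.5 is 0,
  1 is +VENC. Vendor-specific phase conventions beyond the standard
  rescale-slope/intercept path are out of scope; the VENC is supplied by
  the user because no vendor-neutral DICOM tag carries it.
- **Stationary tissue** is detected as temporal SD of velocity below a
  threshold (default 2 % of VENC) with a magnitude floor (default 10 %
  of the maximum time-mean magnitude) to reject air, where phase is
  noise. The vessel ROIs being quantified are always excluded (dilated
  by 2 px): slowly or steadily flowing blood has near-zero temporal SD
  and would otherwise contaminate the fit. This mirrors the manual-ROI
  override that clinical practice uses.
- **Background surface**: a 2D polynomial (order 1–3) least-squares fit
  to the time-mean velocity over the stationary mask, with pixel
  coordinates centered on the image center for conditioning. The fitted
  surface is static in time and subtracted from every frame, consistent
  with eddy-current/Maxwell offsets being temporally constant.
- **Temporal unwrapping**: per pixel, frame-to-frame velocity jumps with
  |Δv| > VENC mark wrap events; opposite-signed events are paired
  greedily left-to-right and 2·VENC (signed against the entering jump)
  is added across the bracketed interval. Pixels with unpaired events
  are left unchanged and flagged rather than guessed at. The procedure
  is idempotent and handles single wraps (|v| < 3·VENC); spatial
  (in-plane) unwrapping is out of scope.
- **Vessel tracking** propagates a frame-0 contour: re-center on the
  intensity-weighted centroid within the previous contour dilated by
  2 px; cast 64 rays and put the new radius at the strongest radial
  gradient within ±30 % of the previous radius (sub-sample localization
  by the gradient-magnitude centroid over the half-peak region, since
  a sharp edge under bilinear sampling yields a gradient plateau whose
  first sample is biased inward); smooth the radii with a circular
  5-tap moving average. The failure flag raises when the area changes
  by more than 50 % between frames or more than 25 % of rays find no
  gradient above the floor (default 0.02 intensity units/px); tracking
  then stops and the last good contour is carried forward.
- **Flow summation**: `Q(t) [ml/s] = Σ v_i(t)[cm/s] · A_pixel[cm²]` over
  pixel centers inside the frame's contour; per-beat volumes integrate
  Q over the cycle with the positive/negative split sharing the same
  summation tree, so net = positive + negative exactly.

## Volumetry and regional function

Slice-summation volumes multiply each delineated slice's polygon area
by the slice step (thickness + gap); no basal/apical partial-slice
correction is applied, which under-resolves the true extremes of a
strongly tapering ventricle — a documented limitation. LV mass is
1.05 g/ml (standard myocardial density) times the epi−endo shell
volume, with epicardial containment of the endocardium enforced as a
type invariant. Wall thickness casts rays from the endocardial centroid
at equally spaced angles (user-supplied reference angle, default 0 =
image "up"); sectors whose ray misses a contour are marked invalid
(NaN), never zero. ED/ES frames are user-designated or taken as the
volume-curve argmax/argmin.

The AHA 17-segment map partitions slices (ordered base→apex) into
thirds, assigning remainder slices apically; basal and mid rings form
6 × 60° segments, the apical ring 4 × 90°, and segment 17 averages the
most apical slice. Segment values are means over contributing samples.

## Resampling and MPR

In-plane resampling uses a separable Keys (Catmull-Rom) bicubic kernel
with two linearly extrapolated padding samples per border, which makes
the interpolator exact on affine signals up to and including the image
edges; downsampling first applies a Gaussian anti-alias filter with
σ = 0.5·(ratio − 1) per axis. Pixel spacing is updated so the physical
extent of the pixel-center grid is preserved exactly. Multi-planar
reconstruction samples the volume trilinearly on an orthonormal oblique
plane — trilinear rather than cubic by design: it is monotone and
cannot overshoot on oblique planes — and returns a validity mask for
out-of-volume samples (filled with 0).

## Phantoms

The flow phantom emulates a gravity-driven rig: a stationary gel block
with two circular channels 26 mm in diameter on a 96×96 grid of 1 mm
pixels, 20 frames of 0.05 s, VENC 200 cm/s, with five per-beat volumes
of 20–100 ml as the default rate ladder. Channel velocity profiles are
Poiseuille (or uniform) scaled so the analytic per-beat integral equals
the requested volume exactly; pixels take the profile value at their
center (no sub-pixel averaging), matching the center-in-polygon
quantification convention so the stored ground truth is exact.
Optional corruptions: a linear background offset plane (defined in
image-center-centered pixel coordinates, matching the fitting
convention), velocity aliasing by modular phase wrap, a sinusoidal
waveform `1 + p·sin(2πt/T)` for pulsatility, Gaussian noise at a
configured SNR (velocity SD = VENC/SNR), and an "air" border with low
magnitude. All generators are seed-deterministic.

The cine LV phantom is a stack of contracting cylinders whose cavity
volume follows a raised-cosine cycle between the configured EDV and ESV
(equal values are allowed and produce a flat curve) with the wall
thickening in antiphase; intensities are quantized to the 12-bit grid
so DICOM fixtures round-trip bit-exactly. The DICOM writer emits one
minimal MR file per (slice, frame) in shuffled order, which is what the
loader's sort logic is validated against.

What these phantoms do **not** emulate: k-space acquisition, partial
volume at vessel rims, motion, flow-related signal enhancement, vendor
phase conventions, or realistic noise correlations. Passing the suite
therefore demonstrates the correctness of the quantification chain, not
the accuracy of any particular scanner's data, where sequences must be
validated individually.

## Numerical choices and degenerate inputs

- Population SD (divide by n) for ROI statistics: the ROI's pixels are
  the full population.
- FWHM: half-maximum is min + (max − min)/2; crossings located by
  linear interpolation between samples; if a flank never crosses, the
  FWHM is reported as undefined with a reason rather than a number.
- Normalized averaging divides the Gaussian-filtered signal·certainty
  by the filtered certainty (kernel truncated at ±4σ), so constants
  pass through exactly at the boundaries; σ = 0 is the identity.
- Background fits require at least 3× as many mask pixels as
  coefficients and reject rank-deficient (e.g. collinear) masks.
- Degenerate ROIs distinguish "outside the image" from "thinner than
  the pixel grid" in their error messages.
- Problem sizes used by tests and the benchmark script (96×96 phantoms,
  5000 sampling-error ROIs, 20-frame cycles) were chosen as the
  smallest sizes at which discretization effects are representative.
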