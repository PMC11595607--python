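# Methods

This note documents the detection model, the choices made where the
design was genuinely open, the synthetic-data model used for validation,
and the known limitations.

## Pipeline model and assumptions

The pipeline assumes spheres are roughly convex, roughly circular objects
that contrast photometrically with the culture medium — in phase contrast
typically a bright body with a darker rim (halo) at the boundary — and
that they are sparse enough not to touch.  Merged or agglomerated spheres
are segmented as one object; splitting them (e.g. by watershed) is out of
scope.

Stage order: grayscale normalization → CLAHE + Gaussian smoothing →
Gabor texture response → ROI proposal → per-ROI segmentation →
artifact filtering → raster numbering → calibrated summary.

Two preprocessed images are kept deliberately:

* the **CLAHE-equalized, smoothed** image feeds the Gabor texture stage,
  where per-tile contrast normalization is exactly what makes wells,
  devices and microscopes comparable;
* the **smoothed-only** image feeds the per-ROI photometric
  segmentation.  CLAHE's tile-wise remapping distorts absolute
  intensities, and a sphere spanning several tiles would get an
  azimuthally uneven rim; segmenting on the un-equalized image keeps
  boundaries photometrically faithful.

## Gabor bank

Kernels follow the analytic form
`g(x,y) = f²/(πγη)·exp(−(x'²f²/γ² + y'²f²/η²))·e^(−j2πfx')` with
x' = x cosθ + y sinθ, y' = −x sinθ + y cosθ, evaluated on the integer
pixel grid (x = column offset, y = row offset).  Defaults: f = [1/4, 1/6,
1/8] cycles/px, θ = 0°..150° in 30° steps, γ = 10, η = 0.5, 21×21
kernels — a full 3 × 6 = 18-kernel grid, every subset configurable.

Two numerical choices:

* **Aggregation** is the per-pixel maximum of complex magnitudes — the
  standard rotation/scale-pooling; the bank is order-invariant under it.
* **DC removal at application time.**  These kernels have a nonzero mean,
  so a uniform region would respond in proportion to its brightness and a
  bright-but-flat area would masquerade as texture (the sphere-to-
  background response ratio saturates at roughly the intensity ratio).
  Each kernel's mean is subtracted before convolution, making the
  response illumination-invariant: flat regions give zero, and the
  in-sphere/background response ratio on synthetic scenes rises from
  ≈1.8 to >30.  Kernel *construction* is unchanged — the analytic center
  value f²/(πγη) still holds for the returned kernels.

## ROI proposal

The aggregate response is min-max normalized; pixels exceeding their
local mean (box of `adaptive_block_fraction`·min-side, default 1/8) by
`roi_response_margin` (default 0.05) are kept, closed with the disk
element, and 8-connected components become ROIs after padding
(`roi_padding_px`, default 8).  Components with either side below
max(16, min-side/64) are discarded — the resolution-dependent floor.  A
perfectly flat response (peak-to-peak < 1e−9) yields no ROIs.

## Per-ROI segmentation and area measurement

The background level of an ROI is estimated as the median of its border
pixels.  Otsu's threshold is applied to the **absolute deviation** from
that level, so bright bodies and dark rims are both foreground under one
rule.  Two guards handle degenerate ROIs:

* **Contrast floor** (`min_roi_contrast`, default 0.1): Otsu always finds
  *a* split, even in pure noise; if the two classes' means differ by less
  than the floor the ROI is treated as background.  Real spheres contrast
  with the medium by far more.
* **Flooding guard**: if the foreground class covers more than 35 % of
  the ROI, the split likely separated two background populations (e.g.
  chamber shadow vs. illuminated medium); the threshold is re-estimated
  with a three-class Otsu and the extreme class kept.

Sobel gradient magnitudes (the two printed 3×3 kernels, reflective
borders), Otsu-thresholded, are OR-ed into the mask — interpreting the
edge stage as a detection aid.  Closing followed by one dilation (disk
element) consolidates each object; 8-connected components of this
detection mask are the candidates.

**Measurement mask.**  Areas and centroids are measured on the
closed-and-dilated *intensity* mask restricted to each component, not on
the edge-augmented mask: a thresholded gradient ring is a boundary
neighborhood, not object interior, and including it biases areas upward
by ~1 px of radius.  The dilation itself is not cosmetic — with a dark
halo rim of width w at the boundary, intensity thresholding recovers only
the core (radius ≈ r − w, further reduced ~0.7 px by the smoothing ramp),
and dilating by the structuring radius restores the full support.  The
default `struct_element_radius_px = 3` matches a 2-px rim plus the ramp
bias at σ = 1 smoothing; imaging with a wider halo should raise it
(configurable).  On synthetic disks this keeps area errors below ~6 %
at r = 10 px, falling below 1 % by r = 40 px.

**Filtering.**  Candidates with area below `min_sphere_area_um2`
(default 300 µm² — debris and erythrocyte clusters are far smaller than
any sphere) or circularity 4πA/P² below `min_circularity` (default 0.4)
are rejected.  Perimeter uses the Crofton approximation.  Duplicates
from overlapping ROIs (mask IoU > 0.5) are merged keeping the larger.

**Numbering** is raster order of integer-rounded centroids, ties broken
by larger area.  It is independent of input order, so the same field
imaged repeatedly yields the same labels — positional tracking with no
motion model.

## Calibration

`microns_per_pixel` is a required user input; areas scale by its square.
No magnification→scale table is hard-coded because the true value depends
on the camera sensor as much as on the objective.  The template config
(`examples/config.toml`) carries pipeline defaults only, with calibration
deliberately left to the CLI flags.

## Synthetic-data model

`synthgen` renders: background (uniform level 0.45, optional linear and
radial gradients), an optional microfluidic chamber (dark ring of width
5 px, shadow depth 0.25, plus half-depth darkening outside), spheres as
antialiased discs — bright core 0.85 with a dark rim (width 2 px,
intensity 0.15) inside the support boundary — small bright speck
clusters (radius 1–2 px, 3–6 per cluster) mimicking erythrocytes, and
finally additive Gaussian noise (default σ = 0.02).  Ground-truth masks
are the noise-free disc supports; their pixel areas are exact counts.
All randomness derives from the scene seed.

Random scenes place non-overlapping spheres with radii drawn from
10–22 px, at least 8 px between boundaries, clear of the image border
and of the chamber wall.  Validation problem sizes: 50 scenes of 1–12
spheres at 320×320 for count recovery; single discs of r = 10/20/40 px
for area recovery (octave-spaced so the 1/r discretization trend is
visible above ±1 px quantization jitter); 1/5/10/20/40 spheres at
640×640 for area-vs-content monotonicity; 10 microfluidic scenes for the
recall floor; noise levels 0.05/0.16/0.30 averaged over 8 scenes for the
difficulty knob.

What the generator does **not** emulate: point-spread-function optics,
out-of-focus blur, uneven focus across a chamber, sphere agglomeration,
texture inside sphere bodies, and debris shapes other than round specks.
Passing these tests therefore demonstrates the pipeline's geometric and
photometric correctness under controlled conditions, not performance on
any particular microscope's images — on real data the contrast floor,
area floor and structuring radius may need adjustment through the config.

## Known limitations

* Touching or agglomerated spheres are counted as one.
* On nonuniform backgrounds, shadows and speck clusters can be accepted
  as objects: precision degrades (over-counting) while recall on true
  spheres stays high — the filters bound, but do not eliminate, false
  positives.
* Severe noise (σ ≳ 0.2 in normalized units) collapses detection rather
  than degrading it gracefully; CLAHE amplifies noise before the texture
  stage.
* Illumination correction (flat-fielding) is not implemented; strongly
  vignetted images should be corrected upstream.
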