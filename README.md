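# spherequant

Automatic detection, numbering, counting and area measurement of
cancer-cell-derived spheres in brightfield / phase-contrast microscopy
images.

Sphere-formation assays enrich for cancer stem cells (CSCs): cells are
seeded at low density in serum-free, anchorage-independent culture, and
only stem-like cells grow into free-floating spheroids.  The readouts —
sphere count, per-sphere area in µm², and sphere formation efficiency
(SFE% = spheres / cells seeded × 100) — are usually obtained by manual
counting and contour drawing, which is slow (minutes per image) and
operator-dependent.  `spherequant` replaces that with a deterministic
pipeline that works on images from multiwell plates (uniform background)
and microfluidic devices (nonuniform background with chamber-wall
shadows), numbers each sphere so it can be tracked across imaging days,
and writes per-detection CSV rows ready for downstream statistics.

## Method

For each image:

1. **Normalize** — RGB is collapsed with BT.601 luma weights; intensities
   are scaled to [0, 1].
2. **Preprocess** — contrast-limited adaptive histogram equalization
   (CLAHE) homogenizes illumination, and a Gaussian filter (σ = 1 px)
   suppresses sensor noise.
3. **Texture response** — a bank of 2D Gabor filters
   `g(x,y) = f²/(πγη) · exp(−(x'²f²/γ² + y'²f²/η²)) · e^(−j2πfx')`
   with frequencies f = [1/4, 1/6, 1/8] cycles/px, six orientations at 30°
   steps, γ = 10, η = 0.5, 21×21 kernels (18 filters) is convolved with the
   image; the per-pixel maximum magnitude is a texture-energy map that
   lights up sphere boundaries and granular interiors.
4. **ROI proposal** — the texture map is adaptively thresholded (local
   mean + margin), closed morphologically, and connected components above
   a resolution-dependent minimum size become rectangular regions of
   interest.
5. **Segmentation per ROI** — Otsu's threshold on the deviation from the
   local background level gives the sphere mask; Sobel gradient magnitudes
   (`G = √(Gx² + Gy²)`), Otsu-thresholded, are OR-ed in to stabilize
   detection; morphological closing + dilation (disk element) consolidate
   each object and recover the dark halo rim that thresholding misses.
6. **Filter & number** — candidates below a physical area floor
   (default 300 µm²) or circularity floor (4πA/P², default 0.4) are
   rejected as debris/erythrocytes; survivors are numbered 1..N in raster
   order of their centroids, a deterministic rule that keeps identities
   stable across repeated imaging of the same field.
7. **Quantify** — pixel areas are converted with the user-supplied
   calibration (area = px · (µm/px)²); per-image totals, percent covered
   area, and SFE% are reported.

A seeded synthetic-scene generator (`spherequant.synthgen`) renders
phase-contrast-like spheres (bright core, dark rim) on uniform or
microfluidic backgrounds with exact ground-truth masks, so the whole
pipeline is validated without any real image data.

## Worked example

Generate two synthetic images with four spheres each, then analyze them:

```bash
spherequant synth --out images --n-images 2 --spheres-per-image 4 --seed 7
spherequant run --input images --output results --magnification 10x --um-per-px 1.0
```

which prints

```
2 images processed, 8 spheres detected
results written to results/results.csv
```

and `results/results.csv` starts

```
image,sphere_id,centroid_row,centroid_col,area_px,area_um2,equivalent_diameter_um,circularity,percent_of_image_area,percent_of_roi_area,touches_border,magnification,microns_per_pixel,error
scene_000.png,1,102.441683,266.229446,523,523.000000,25.805121,0.992327,0.510742,16.097261,False,10x,1.000000,
scene_000.png,2,104.456494,97.480454,793,793.000000,31.775446,0.991590,0.774414,20.302099,False,10x,1.000000,
```

Each detection row gives the sphere's label (the red number drawn on
`scene_000_annotated.png`), centroid, pixel and calibrated µm² area,
equivalent diameter, circularity, and its area as a percentage of the
image and of its ROI; a final row per image summarizes the totals.  At
1 µm/px, sphere 1 covers 523 µm² (equivalent diameter ≈ 25.8 µm) —
0.51 % of the image.  All eight generated spheres are recovered.

The calibration (`--um-per-px`) is deliberately a required input: the
true scale depends on the objective *and* the camera sensor, so it must
come from your microscope's calibration slide, never from a default.
Note that the minimum sphere area is physical (µm²), so the same image
analyzed at a finer scale may correctly reject small objects as debris.

Library use mirrors the CLI:

```python
from spherequant import Calibration, PipelineConfig, analyze_image, read_image

cal = Calibration(magnification="10x", microns_per_pixel=0.65)
report = analyze_image(read_image("well_03.png"), PipelineConfig(), cal)
print(report.sphere_count, report.total_area_um2)
```

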