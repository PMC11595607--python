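# Template pipeline configuration for `spherequant run --config FILE`.
# Every key is optional; omitted keys keep the library defaults shown here.
#
# NOTE ON CALIBRATION: the micron-per-pixel scale is NOT part of this file
# and has no safe default — it depends on your objective AND camera sensor.
# Measure it with a calibration slide and pass it per run:
#     spherequant run ... --magnification 10x --um-per-px <YOUR VALUE>

# --- preprocessing ---------------------------------------------------------
clahe_clip_limit = 0.01          # fraction in (0, 1]
clahe_tile_grid = [8, 8]         # [rows, cols]
gaussian_sigma = 1.0             # px

# --- Gabor texture bank ----------------------------------------------------
gabor_frequencies = [0.25, 0.16666666666666666, 0.125]   # cycles/px
gabor_orientations_deg = [0, 30, 60, 90, 120, 150]
gabor_gamma = 10.0
gabor_eta = 0.5
gabor_kernel_size = 21           # odd px

# --- ROI proposal ----------------------------------------------------------
roi_min_side_px = 0              # 0 = auto: max(16, min(h, w) // 64)
roi_padding_px = 8
adaptive_block_fraction = 0.125  # local-mean window as fraction of min side
roi_response_margin = 0.05

# --- segmentation and filtering -------------------------------------------
struct_element_radius_px = 3     # match to your halo rim width + 1
adaptive_offset = 0.02           # intensity units
min_roi_contrast = 0.1           # intensity units
min_sphere_area_um2 = 300.0      # physical debris floor
min_circularity = 0.4            # 4*pi*A/P^2
use_edge_union = true            # OR Sobel edges into the detection mask
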