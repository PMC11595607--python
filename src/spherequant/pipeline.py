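"""End-to-end analysis of a single image.

Stage order: grayscale normalization -> CLAHE + Gaussian smoothing ->
Gabor texture response -> ROI proposal -> per-ROI segmentation (Otsu +
Sobel edges + morphology) -> artifact filtering -> raster numbering ->
calibrated summary.
"""

from __future__ import annotations

import time

from .core import Calibration, GrayImage, MIN_PIPELINE_SIDE, PipelineConfig
from .detect import extract_spheres, number_spheres, propose_rois
from .gabor import apply_gabor_bank, build_gabor_bank
from .preprocess import clahe, gaussian_smooth
from .quantify import ImageReport, summarize


def analyze_image(
    image: GrayImage, cfg: PipelineConfig, cal: Calibration
) -> ImageReport:
    """Run the full detection pipeline on one grayscale image."""
    if image.height < MIN_PIPELINE_SIDE or image.width < MIN_PIPELINE_SIDE:
        raise ValueError(
            f"image {image.source_path or '<memory>'} is "
            f"{image.height}x{image.width}; pipeline requires at least "
            f"{MIN_PIPELINE_SIDE}x{MIN_PIPELINE_SIDE}"
        )
    t0 = time.perf_counter()
    # CLAHE homogenizes contrast for the texture stage; the per-ROI
    # photometric segmentation runs on the smoothed image without CLAHE so
    # tile-wise remapping cannot distort sphere boundaries.
    enhanced = gaussian_smooth(
        clahe(image, cfg.clahe_clip_limit, cfg.clahe_tile_grid),
        cfg.gaussian_sigma,
    )
    smoothed = gaussian_smooth(image, cfg.gaussian_sigma)
    bank = build_gabor_bank(cfg.gabor_spec)
    response = apply_gabor_bank(enhanced, bank)
    rois = propose_rois(response, cfg)
    detections = number_spheres(extract_spheres(smoothed, rois, cfg, cal))
    elapsed = time.perf_counter() - t0
    return summarize(image, detections, cal, processing_time_s=elapsed)
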