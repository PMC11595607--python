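"""Contrast homogenization and denoising.

Phase-contrast sphere images vary strongly in illumination between wells,
devices and microscopes.  Contrast-limited adaptive histogram equalization
(CLAHE) flattens those differences per tile, and a Gaussian filter removes
sensor noise, so that the downstream texture and edge stages see comparable
inputs regardless of acquisition conditions.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.ndimage as ndi
from skimage import exposure

from .core import GrayImage

logger = logging.getLogger(__name__)

#: Gaussian kernels are truncated at this many standard deviations.
GAUSSIAN_TRUNCATE = 4.0


def clahe(
    image: GrayImage,
    clip_limit: float = 0.01,
    tile_grid: tuple[int, int] = (8, 8),
) -> GrayImage:
    """Contrast-limited adaptive histogram equalization.

    The image is divided into ``tile_grid`` tiles; each tile's histogram is
    equalized with the given clip limit, and tile mappings are blended by
    bilinear interpolation.  If a requested tile would be smaller than one
    pixel the grid falls back to a single global tile (with a warning).

    Parameters
    ----------
    clip_limit
        Fraction in ``(0, 1]`` limiting per-bin histogram mass; small
        values suppress noise amplification.
    tile_grid
        ``(rows, cols)`` of the tile grid.
    """
    if not 0 < clip_limit <= 1:
        raise ValueError(f"clip_limit must be in (0, 1], got {clip_limit}")
    rows, cols = tile_grid
    if rows < 1 or cols < 1:
        raise ValueError(f"tile_grid dims must be >= 1, got {tile_grid}")

    px = image.pixels
    if float(np.ptp(px)) < 1e-12:
        # Degenerate histogram: no contrast to redistribute.
        return image.with_pixels(px.copy())

    kr, kc = image.height // rows, image.width // cols
    if kr < 1 or kc < 1:
        logger.warning(
            "CLAHE tile grid %s too fine for image %dx%d; falling back to a "
            "single global tile",
            tile_grid,
            image.height,
            image.width,
        )
        kr, kc = image.height, image.width
    out = exposure.equalize_adapthist(
        px, kernel_size=(kr, kc), clip_limit=clip_limit
    )
    return image.with_pixels(np.clip(out, 0.0, 1.0))


def gaussian_smooth(image: GrayImage, sigma: float = 1.0) -> GrayImage:
    """Smooth with a normalized isotropic Gaussian kernel.

    Uses reflective boundary handling, so the mean intensity of
    interior-dominated images is preserved.  The kernel is truncated at
    4 sigma.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    out = ndi.gaussian_filter(
        image.pixels, sigma=sigma, mode="reflect", truncate=GAUSSIAN_TRUNCATE
    )
    return image.with_pixels(np.clip(out, 0.0, 1.0))
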