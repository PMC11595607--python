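"""Domain types, calibration and pipeline configuration.

Coordinate convention used throughout the package: images are 2D rasters
indexed ``(row, column)`` with the origin at the top-left pixel; row indices
increase downward, column indices increase rightward.  Bounding boxes are
half-open, ``[r0, r1) x [c0, c1)``, and 0-based.  Intensities are normalized
to ``[0, 1]`` on load; the original bit depth is retained as metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .gabor import GaborBankSpec

#: ITU-R BT.601 luma weights used for RGB -> gray conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Minimum side length (pixels) for an image entering the full pipeline.
MIN_PIPELINE_SIDE = 16


@dataclass
class GrayImage:
    """A single-channel intensity raster with values in ``[0, 1]``.

    Parameters
    ----------
    pixels
        2D float array of intensities in ``[0, 1]``.
    source_path
        Originating file, or ``""`` for in-memory images.
    bit_depth_original
        Bit depth of the source samples before normalization (metadata only).
    """

    pixels: np.ndarray
    source_path: str = ""
    bit_depth_original: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(
                f"GrayImage requires a 2D raster, got shape {self.pixels.shape}"
            )
        if self.pixels.size == 0:
            raise ValueError("GrayImage must be non-empty")
        lo = float(self.pixels.min())
        hi = float(self.pixels.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(
                f"intensities must lie in [0, 1]; got range [{lo}, {hi}]"
            )
        np.clip(self.pixels, 0.0, 1.0, out=self.pixels)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def with_pixels(self, pixels: np.ndarray) -> "GrayImage":
        """Return a copy of this image with new pixel data, same metadata."""
        return GrayImage(
            pixels=pixels,
            source_path=self.source_path,
            bit_depth_original=self.bit_depth_original,
        )


@dataclass(frozen=True)
class Calibration:
    """Mapping from objective magnification to physical pixel size.

    The true microns-per-pixel value depends on the objective *and* the
    camera sensor, so it must be supplied by the user; it is never
    defaulted silently.
    """

    magnification: str
    microns_per_pixel: float

    def __post_init__(self) -> None:
        if not self.microns_per_pixel > 0:
            raise ValueError(
                f"microns_per_pixel must be > 0, got {self.microns_per_pixel}"
            )

    @property
    def area_scale_um2_per_px(self) -> float:
        """Area conversion factor, um^2 per pixel (= microns_per_pixel**2)."""
        return self.microns_per_pixel ** 2


def _default_gabor_spec():
    from .gabor import GaborBankSpec

    return GaborBankSpec()


@dataclass
class PipelineConfig:
    """Every tunable of the sphere-detection pipeline, with defaults.

    Lengths are in pixels, areas in um^2 (converted with the run's
    :class:`Calibration`), intensities in normalized ``[0, 1]`` units.
    """

    clahe_clip_limit: float = 0.01
    clahe_tile_grid: tuple[int, int] = (8, 8)
    gaussian_sigma: float = 1.0
    gabor_spec: "GaborBankSpec" = field(default_factory=_default_gabor_spec)
    #: 0 means "auto": max(16, min(height, width) // 64).
    roi_min_side_px: int = 0
    roi_padding_px: int = 8
    min_sphere_area_um2: float = 300.0
    min_circularity: float = 0.4
    struct_element_radius_px: int = 3
    adaptive_block_fraction: float = 1.0 / 8.0
    adaptive_offset: float = 0.02
    #: margin over the local mean of the normalized texture response that a
    #: pixel must exceed to seed an ROI.
    roi_response_margin: float = 0.05
    #: minimum Otsu class-mean separation (intensity units) for an ROI to
    #: contain foreground at all; guards against pure-noise regions.
    min_roi_contrast: float = 0.1
    #: Whether thresholded Sobel edges are OR-ed into the detection mask.
    use_edge_union: bool = True
    #: Used only by synthetic generation.
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.clahe_clip_limit <= 1:
            raise ValueError("clahe_clip_limit must be in (0, 1]")
        if min(self.clahe_tile_grid) < 1:
            raise ValueError("clahe_tile_grid dims must be >= 1")
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be > 0")
        if self.roi_min_side_px < 0 or self.roi_padding_px < 0:
            raise ValueError("ROI sizes must be non-negative")
        if self.min_sphere_area_um2 <= 0:
            raise ValueError("min_sphere_area_um2 must be > 0")
        if not 0 <= self.min_circularity <= 1:
            raise ValueError("min_circularity must be in [0, 1]")
        if self.struct_element_radius_px < 1:
            raise ValueError("struct_element_radius_px must be >= 1")
        if not 0 < self.adaptive_block_fraction < 1:
            raise ValueError("adaptive_block_fraction must be in (0, 1)")

    def roi_min_side(self, height: int, width: int) -> int:
        """Resolution-dependent minimum ROI side length."""
        if self.roi_min_side_px > 0:
            return self.roi_min_side_px
        return max(MIN_PIPELINE_SIDE, min(height, width) // 64)


def to_gray(image: np.ndarray, source_path: str = "") -> GrayImage:
    """Convert an RGB or already-gray raster to a normalized :class:`GrayImage`.

    Integer samples are rescaled by their dtype's full range; float samples
    are assumed to already be in ``[0, 1]``.  Three-channel input is combined
    with fixed BT.601 luma weights (0.299, 0.587, 0.114); single-channel
    input is only rescaled.

    Raises
    ------
    ValueError
        If the channel count is not 1 or 3.
    """
    arr = np.asarray(image)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.ndim not in (2, 3) or (arr.ndim == 3 and arr.shape[2] != 3):
        where = f" ({source_path})" if source_path else ""
        raise ValueError(
            f"unsupported channel layout{where}: expected 1 or 3 channels, "
            f"got array of shape {arr.shape}"
        )

    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        bit_depth = info.bits
        scaled = arr.astype(np.float64) / float(info.max)
    elif arr.dtype == bool:
        bit_depth = 1
        scaled = arr.astype(np.float64)
    else:
        bit_depth = 8 * arr.dtype.itemsize
        scaled = np.clip(arr.astype(np.float64), 0.0, 1.0)

    if scaled.ndim == 3:
        w = np.asarray(LUMA_WEIGHTS, dtype=np.float64)
        scaled = scaled @ w
    return GrayImage(
        pixels=scaled, source_path=source_path, bit_depth_original=bit_depth
    )


def pixels_to_um2(area_px: float, cal: Calibration) -> float:
    """Convert a pixel count into a physical area in um^2.

    ``area_um2 = area_px * microns_per_pixel**2``.
    """
    if area_px < 0:
        raise ValueError(f"area_px must be >= 0, got {area_px}")
    return float(area_px) * cal.area_scale_um2_per_px
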