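"""Edge detection, thresholding and morphological cleanup.

These are the operators that turn a contrast-homogenized sub-image into a
binary sphere mask: Sobel gradients highlight sphere borders, Otsu's method
picks the intensity threshold separating sphere from background within a
region, an adaptive (local-mean) threshold handles nonuniform backgrounds
during region proposal, and closing + dilation consolidate the foreground.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage import morphology

from .core import GrayImage

SOBEL_KX = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
SOBEL_KY = np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=np.float64)


class DegenerateHistogramError(ValueError):
    """Raised when a threshold is requested for a constant image."""


def _as_array(image) -> np.ndarray:
    if isinstance(image, GrayImage):
        return image.pixels
    return np.asarray(image, dtype=np.float64)


@dataclass
class GradientField:
    """Sobel gradient of an image.

    ``G = sqrt(Gx^2 + Gy^2)`` is the gradient magnitude and
    ``theta = atan2(Gy, Gx)`` the gradient direction in ``(-pi, pi]``.
    """

    Gx: np.ndarray
    Gy: np.ndarray
    G: np.ndarray
    theta: np.ndarray


@dataclass
class BinaryMask:
    """A boolean foreground raster."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("BinaryMask requires a 2D raster")

    @property
    def foreground_count(self) -> int:
        return int(self.pixels.sum())


def sobel(image) -> GradientField:
    """Sobel gradient via convolution with the two 3x3 derivative kernels.

    ``Gx`` approximates the horizontal derivative, ``Gy`` the vertical one
    (``Gy`` is the transpose kernel of ``Gx``).  Reflective borders.
    """
    arr = _as_array(image)
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError(f"image must be at least 3x3, got {arr.shape}")
    gx = ndi.convolve(arr, SOBEL_KX, mode="reflect")
    gy = ndi.convolve(arr, SOBEL_KY, mode="reflect")
    g = np.hypot(gx, gy)
    theta = np.arctan2(gy, gx)
    return GradientField(Gx=gx, Gy=gy, G=g, theta=theta)


def otsu_threshold(image, n_bins: int = 256) -> float:
    """Otsu's threshold: maximize between-class variance of the histogram.

    The histogram has ``n_bins`` equal bins spanning the image's intensity
    range.  Candidate thresholds are interior bin edges; the class split
    puts bins at or below the candidate edge in the low class.  Ties are
    broken by the lowest qualifying threshold, making the result fully
    deterministic.

    Raises
    ------
    DegenerateHistogramError
        If the image is constant (callers treat the whole region as
        background).
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    arr = _as_array(image)
    lo, hi = float(arr.min()), float(arr.max())
    if hi - lo < 1e-12:
        raise DegenerateHistogramError(
            "constant image has no threshold separating two classes"
        )
    hist, edges = np.histogram(arr, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist = hist.astype(np.float64)
    total = hist.sum()

    w0 = np.cumsum(hist)[:-1]  # low-class mass for split after bin k
    w1 = total - w0
    mass = np.cumsum(hist * centers)[:-1]
    mu_total = float((hist * centers).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mass / w0
        mu1 = (mu_total - mass) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b, nan=-np.inf)
    k = int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximizer
    return float(edges[k + 1])


def adaptive_threshold(image, block_size: int, offset: float) -> BinaryMask:
    """Local-mean thresholding for nonuniform backgrounds.

    A pixel is foreground iff its intensity exceeds the mean over the
    ``block_size`` x ``block_size`` neighborhood minus ``offset`` (local
    means use reflective borders).
    """
    if block_size < 3 or block_size % 2 == 0:
        raise ValueError(f"block_size must be odd and >= 3, got {block_size}")
    arr = _as_array(image)
    local_mean = ndi.uniform_filter(arr, size=block_size, mode="reflect")
    return BinaryMask(pixels=arr > local_mean - offset)


def _padded_disk_op(mask: np.ndarray, radius: int, op) -> np.ndarray:
    # Pad so morphology near the border behaves as on an infinite
    # background; keeps closing extensive on the full raster.
    selem = morphology.disk(radius).astype(bool)
    pad = 2 * radius
    padded = np.pad(mask, pad, mode="constant", constant_values=False)
    return op(padded, structure=selem)[pad:-pad, pad:-pad]


def morph_close(mask: BinaryMask, radius: int = 2) -> BinaryMask:
    """Morphological closing with a disk structuring element."""
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    return BinaryMask(
        pixels=_padded_disk_op(mask.pixels, radius, ndi.binary_closing)
    )


def morph_close_dilate(mask: BinaryMask, radius: int = 2) -> BinaryMask:
    """Closing followed by one dilation, disk structuring element.

    Closing fills background holes inside foreground regions; the extra
    dilation enlarges foreground boundaries.  Both operations are
    extensive, so the output always contains the input.
    """
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    closed = _padded_disk_op(mask.pixels, radius, ndi.binary_closing)
    out = _padded_disk_op(closed, radius, ndi.binary_dilation)
    return BinaryMask(pixels=out)
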