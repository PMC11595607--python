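"""Gabor filter bank for texture-based sphere-region enhancement.

A 2D Gabor filter is a complex sinusoid (carrier) modulated by an elliptic
Gaussian envelope:

    g(x, y) = (f^2 / (pi * gamma * eta))
              * exp(-(x'^2 f^2 / gamma^2 + y'^2 f^2 / eta^2))
              * exp(-j 2 pi f x')

with rotated coordinates x' = x cos(theta) + y sin(theta),
y' = -x sin(theta) + y cos(theta).  ``f`` is the carrier frequency
(cycles/pixel), ``gamma`` and ``eta`` set the envelope sharpness along the
major and minor axes.  A bank over several frequencies and orientations
gives texture-selective responses that light up the granular interior of
spheres while leaving flat background quiet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .core import GrayImage

_DEFAULT_FREQUENCIES = (1 / 4, 1 / 6, 1 / 8)
_DEFAULT_ORIENTATIONS = tuple(np.deg2rad([0, 30, 60, 90, 120, 150]))


@dataclass(frozen=True)
class GaborBankSpec:
    """Parameters of the Gabor filter bank.

    Defaults: three frequencies ``[1/4, 1/6, 1/8]`` cycles/px, six
    orientations at 30-degree steps, ``gamma = 10``, ``eta = 0.5``, and a
    21 x 21 kernel — 18 kernels in total.
    """

    frequencies: tuple[float, ...] = _DEFAULT_FREQUENCIES
    orientations: tuple[float, ...] = _DEFAULT_ORIENTATIONS
    gamma: float = 10.0
    eta: float = 0.5
    kernel_size: int = 21

    def __post_init__(self) -> None:
        if len(self.frequencies) == 0 or len(self.orientations) == 0:
            raise ValueError("frequencies and orientations must be non-empty")
        if any(f <= 0 for f in self.frequencies):
            raise ValueError("all frequencies must be > 0")
        if self.kernel_size < 3 or self.kernel_size % 2 == 0:
            raise ValueError(
                f"kernel_size must be odd and >= 3, got {self.kernel_size}"
            )
        if self.gamma <= 0 or self.eta <= 0:
            raise ValueError("gamma and eta must be > 0")

    @property
    def n_filters(self) -> int:
        return len(self.frequencies) * len(self.orientations)


@dataclass
class GaborResponse:
    """Magnitude responses of the bank applied to one image.

    ``per_filter`` stacks one 2D magnitude raster per (frequency,
    orientation) pair; ``aggregate`` is the per-pixel maximum over the
    stack, an orientation- and scale-pooled texture-energy map.
    """

    per_filter: np.ndarray  # (n_filters, H, W), magnitudes >= 0
    aggregate: np.ndarray = field(init=False)  # (H, W)

    def __post_init__(self) -> None:
        self.per_filter = np.asarray(self.per_filter, dtype=np.float64)
        if self.per_filter.ndim != 3:
            raise ValueError("per_filter must be a (n, H, W) stack")
        self.aggregate = self.per_filter.max(axis=0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.aggregate.shape


def build_gabor_bank(spec: GaborBankSpec) -> list[np.ndarray]:
    """Construct the complex kernels of the bank.

    Kernels are evaluated on the integer pixel grid centered at the kernel
    midpoint, with ``x`` the column offset and ``y`` the row offset.  One
    kernel is produced per (frequency, orientation) pair, frequency-major
    order; the center value of each kernel is ``f^2 / (pi * gamma * eta)``.
    """
    half = spec.kernel_size // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    kernels: list[np.ndarray] = []
    for f in spec.frequencies:
        for theta in spec.orientations:
            xp = x * np.cos(theta) + y * np.sin(theta)
            yp = -x * np.sin(theta) + y * np.cos(theta)
            envelope = np.exp(
                -(xp**2 * f**2 / spec.gamma**2 + yp**2 * f**2 / spec.eta**2)
            )
            carrier = np.exp(-2j * np.pi * f * xp)
            amplitude = f**2 / (np.pi * spec.gamma * spec.eta)
            kernels.append(amplitude * envelope * carrier)
    return kernels


def apply_gabor_bank(image: GrayImage, bank: list[np.ndarray]) -> GaborResponse:
    """Convolve the image with every kernel and take complex magnitudes.

    Convolution (not correlation) with the complex kernel, reflective
    borders; the magnitude is taken after filtering.  Each kernel's mean
    (DC component) is subtracted before convolution, so a uniform region
    responds with zero regardless of its brightness — without this the
    response would scale with local intensity and bright-but-flat areas
    would masquerade as texture.  Deterministic.
    """
    if not bank:
        raise ValueError("bank must contain at least one kernel")
    k = bank[0].shape[0]
    if image.height < k or image.width < k:
        raise ValueError(
            f"image shape ({image.height}, {image.width}) is smaller than "
            f"the {k}x{k} kernel"
        )
    half = k // 2
    padded = np.pad(image.pixels, half, mode="reflect")
    responses = np.empty((len(bank), image.height, image.width))
    for i, kernel in enumerate(bank):
        conv = fftconvolve(padded, kernel - kernel.mean(), mode="same")
        responses[i] = np.abs(conv[half:-half, half:-half])
    return GaborResponse(per_filter=responses)
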