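"""Per-image summaries and sphere formation efficiency.

Sphere formation efficiency (SFE) is the percentage of seeded cells that
grew into a sphere:

    SFE% = (number of spheres / number of cells seeded) * 100

It is the standard readout of sphere-formation assays used to compare
stemness across treatments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import Calibration, GrayImage
from .detect import SphereDetection


@dataclass
class ImageReport:
    """Aggregated result of processing one image."""

    source_path: str
    magnification: str
    sphere_count: int
    detections: list[SphereDetection]
    total_area_um2: float
    #: percentage of the *full image* area covered by detections, in [0, 100]
    percent_area: float
    processing_time_s: float = 0.0
    error: str = ""


@dataclass(frozen=True)
class SFEResult:
    n_spheres: int
    n_seeded: int
    sfe_percent: float


def summarize(
    image: GrayImage,
    detections: list[SphereDetection],
    cal: Calibration,
    processing_time_s: float = 0.0,
) -> ImageReport:
    """Aggregate detections into an :class:`ImageReport`.

    ``percent_area`` is total detected pixel area over full image area
    (each detection also carries its own ROI for per-ROI fractions).
    """
    total_px = sum(d.area_px for d in detections)
    total_um2 = sum(d.area_um2 for d in detections)
    percent = 100.0 * total_px / (image.height * image.width)
    return ImageReport(
        source_path=image.source_path,
        magnification=cal.magnification,
        sphere_count=len(detections),
        detections=list(detections),
        total_area_um2=total_um2,
        percent_area=percent,
        processing_time_s=processing_time_s,
    )


def sphere_formation_efficiency(n_spheres: int, n_seeded: int) -> SFEResult:
    """SFE% = 100 * n_spheres / n_seeded."""
    if n_seeded <= 0:
        raise ValueError(f"n_seeded must be > 0, got {n_seeded}")
    if n_spheres < 0:
        raise ValueError(f"n_spheres must be >= 0, got {n_spheres}")
    return SFEResult(
        n_spheres=n_spheres,
        n_seeded=n_seeded,
        sfe_percent=100.0 * n_spheres / n_seeded,
    )
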