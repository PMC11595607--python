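"""ROI proposal, per-ROI sphere extraction, artifact filtering, numbering.

The detection strategy follows the texture-first design: the Gabor
aggregate response proposes rectangular regions of interest (ROIs), then
within each ROI an Otsu intensity mask and thresholded Sobel edges are
combined, cleaned morphologically, and connected components become sphere
candidates.  Candidates smaller than a physical area floor or less round
than a circularity floor are rejected — this removes debris and
erythrocyte-like specks that would otherwise inflate the count.
Detections are finally numbered in raster order of their centroids, a
deterministic rule that keeps a sphere's identity stable across repeated
imaging of the same field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage import measure

from .core import Calibration, GrayImage, PipelineConfig, pixels_to_um2
from .gabor import GaborResponse
from .segment import (
    BinaryMask,
    DegenerateHistogramError,
    _padded_disk_op,
    adaptive_threshold,
    morph_close_dilate,
    otsu_threshold,
    sobel,
)

_EIGHT_CONN = np.ones((3, 3), dtype=bool)

#: Foreground fraction above which the ROI threshold is re-estimated with a
#: three-class split (guards against a bimodal background swallowing the ROI).
_MAX_FOREGROUND_FRACTION = 0.35


@dataclass(frozen=True)
class RegionOfInterest:
    """Half-open box (r0, r1) x (c0, c1) in full-image coordinates."""

    r0: int
    r1: int
    c0: int
    c1: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (self.r1 > self.r0 and self.c1 > self.c0):
            raise ValueError(f"degenerate ROI box {self.box}")

    @property
    def box(self) -> tuple[int, int, int, int]:
        return (self.r0, self.r1, self.c0, self.c1)

    @property
    def height(self) -> int:
        return self.r1 - self.r0

    @property
    def width(self) -> int:
        return self.c1 - self.c0

    @property
    def area_px(self) -> int:
        return self.height * self.width


@dataclass
class SphereDetection:
    """One detected sphere with calibrated measurements.

    ``label`` is assigned by :func:`number_spheres`; until then it is 0.
    ``contour`` is a closed, ordered list of (row, col) boundary points in
    full-image coordinates.
    """

    centroid: tuple[float, float]
    area_px: int
    area_um2: float
    circularity: float
    equivalent_diameter_um: float
    contour: np.ndarray
    touches_border: bool
    roi_index: int
    roi_area_px: int
    label: int = 0
    bbox: tuple[int, int, int, int] = (0, 0, 0, 0)  # global, half-open
    mask: np.ndarray = field(default_factory=lambda: np.zeros((0, 0), bool))


def propose_rois(
    response: GaborResponse, cfg: PipelineConfig
) -> list[RegionOfInterest]:
    """Propose ROIs from the aggregate texture response.

    The aggregate is min-max normalized and thresholded against its local
    mean plus a margin, closed morphologically, and 8-connected components
    are taken.  Component boxes with either side below the
    resolution-dependent minimum are discarded; surviving boxes are padded
    and clipped to the image.  ROIs are sorted by (r0, c0).
    """
    agg = response.aggregate
    h, w = agg.shape
    if float(np.ptp(agg)) < 1e-9:
        return []  # no texture anywhere
    norm = (agg - agg.min()) / np.ptp(agg)

    block = int(round(cfg.adaptive_block_fraction * min(h, w)))
    block = max(3, block | 1)  # force odd
    # negative offset: pixel must exceed the local mean by the margin
    mask = adaptive_threshold(norm, block, -cfg.roi_response_margin).pixels

    mask = _padded_disk_op(
        mask, cfg.struct_element_radius_px, ndi.binary_closing
    )
    labels, n = ndi.label(mask, structure=_EIGHT_CONN)
    min_side = cfg.roi_min_side(h, w)
    pad = cfg.roi_padding_px

    rois: list[RegionOfInterest] = []
    for sl in ndi.find_objects(labels):
        if sl is None:
            continue
        rs, cs = sl
        if (rs.stop - rs.start) < min_side or (cs.stop - cs.start) < min_side:
            continue
        r0 = max(0, rs.start - pad)
        r1 = min(h, rs.stop + pad)
        c0 = max(0, cs.start - pad)
        c1 = min(w, cs.stop + pad)
        score = float(agg[r0:r1, c0:c1].mean())
        rois.append(RegionOfInterest(r0, r1, c0, c1, score))
    rois.sort(key=lambda r: (r.r0, r.c0))
    return rois


def _roi_foreground(
    sub: np.ndarray, min_contrast: float = 0.1
) -> np.ndarray | None:
    """Binary sphere mask of one ROI from Otsu's threshold.

    Spheres may be brighter or darker than the medium, and phase-contrast
    spheres show both at once (bright body, dark halo rim).  The ROI is
    therefore thresholded on the absolute deviation from the background
    level, estimated as the median of the ROI border pixels: Otsu's method
    on the deviation image separates "deviates from background" (sphere
    body and rim alike) from "background".  If that foreground floods most
    of the ROI — a sign the split separated two background populations,
    e.g. chamber shadow vs. illuminated medium — the threshold is
    re-estimated with a three-class Otsu split and the extreme class kept.
    """
    border = np.concatenate([sub[0], sub[-1], sub[1:-1, 0], sub[1:-1, -1]])
    deviation = np.abs(sub - float(np.median(border)))
    try:
        t = otsu_threshold(deviation)
    except DegenerateHistogramError:
        return None
    fg = deviation > t
    if not fg.any():
        return None
    # Contrast floor: Otsu always finds *a* split, even in pure noise.  An
    # ROI whose two classes differ by less than min_contrast contains no
    # object — spheres contrast strongly with the culture medium.
    if float(deviation[fg].mean() - deviation[~fg].mean()) < min_contrast:
        return None

    if fg.mean() > _MAX_FOREGROUND_FRACTION:
        from skimage.filters import threshold_multiotsu

        try:
            thresholds = threshold_multiotsu(deviation, classes=3)
        except ValueError:
            return fg
        fg3 = deviation > thresholds[-1]
        if 0 < fg3.mean() < fg.mean():
            fg = fg3
    return fg


def _trace_contour(comp_mask: np.ndarray, offset: tuple[int, int]) -> np.ndarray:
    padded = np.pad(comp_mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return np.zeros((0, 2))
    longest = max(contours, key=len)
    return longest - 1.0 + np.asarray(offset, dtype=np.float64)


def extract_spheres(
    image: GrayImage,
    rois: list[RegionOfInterest],
    cfg: PipelineConfig,
    cal: Calibration,
) -> list[SphereDetection]:
    """Segment spheres inside each ROI and pool the results.

    Per ROI: Otsu intensity mask, union with Otsu-thresholded Sobel edge
    magnitudes, then closing + dilation with a disk element; 8-connected
    components of the result are candidate spheres.  Component areas and
    centroids are measured on the closed-and-dilated *intensity* mask
    (the dilation recovers the dark halo rim that intensity thresholding
    misses); the edge union only steers detection.  Candidates with
    ``area_um2`` below the floor or circularity below the minimum are
    discarded.  Detections duplicated across overlapping ROIs (mask IoU
    > 0.5) are merged keeping the larger.
    """
    h, w = image.height, image.width
    detections: list[SphereDetection] = []
    for roi_index, roi in enumerate(rois):
        if roi.r0 < 0 or roi.c0 < 0 or roi.r1 > h or roi.c1 > w:
            raise ValueError(f"ROI {roi.box} out of image bounds ({h}, {w})")
        sub = image.pixels[roi.r0 : roi.r1, roi.c0 : roi.c1]
        fg = _roi_foreground(sub, cfg.min_roi_contrast)
        if fg is None:
            continue

        mask = fg
        if cfg.use_edge_union:
            grad = sobel(sub)
            try:
                t_g = otsu_threshold(grad.G)
                mask = mask | (grad.G > t_g)
            except DegenerateHistogramError:
                pass

        radius = cfg.struct_element_radius_px
        # Detection mask: intensity + edges, closed and dilated — maximal
        # support for finding and separating objects.  Measurement mask:
        # intensity only, closed and dilated — the dilation restores the
        # dark halo rim that thresholding misses, while the edge ring is
        # excluded because a thresholded gradient band is a boundary
        # neighborhood, not object interior.
        dilated = morph_close_dilate(BinaryMask(mask), radius).pixels
        meas_base = morph_close_dilate(BinaryMask(fg), radius).pixels
        labels, n = ndi.label(dilated, structure=_EIGHT_CONN)
        for lab, sl in enumerate(ndi.find_objects(labels), start=1):
            if sl is None:
                continue
            comp = labels[sl] == lab
            meas = meas_base[sl] & comp
            if not meas.any():
                meas = comp
            area_px = int(meas.sum())
            area_um2 = pixels_to_um2(area_px, cal)
            perimeter = measure.perimeter_crofton(meas, directions=4)
            circularity = (
                4 * np.pi * area_px / perimeter**2 if perimeter > 0 else 1.0
            )
            if area_um2 < cfg.min_sphere_area_um2:
                continue
            if circularity < cfg.min_circularity:
                continue
            rr, cc = np.nonzero(meas)
            g_r0 = roi.r0 + sl[0].start
            g_c0 = roi.c0 + sl[1].start
            centroid = (g_r0 + float(rr.mean()), g_c0 + float(cc.mean()))
            bbox = (
                g_r0,
                roi.r0 + sl[0].stop,
                g_c0,
                roi.c0 + sl[1].stop,
            )
            touches = (
                bbox[0] <= 0 or bbox[2] <= 0 or bbox[1] >= h or bbox[3] >= w
            )
            contour = _trace_contour(meas, (g_r0, g_c0))
            detections.append(
                SphereDetection(
                    centroid=centroid,
                    area_px=area_px,
                    area_um2=area_um2,
                    circularity=float(circularity),
                    equivalent_diameter_um=2.0 * float(np.sqrt(area_um2 / np.pi)),
                    contour=contour,
                    touches_border=touches,
                    roi_index=roi_index,
                    roi_area_px=roi.area_px,
                    bbox=bbox,
                    mask=meas,
                )
            )
    return _merge_duplicates(detections)


def _mask_iou(a: SphereDetection, b: SphereDetection) -> float:
    r0 = max(a.bbox[0], b.bbox[0])
    r1 = min(a.bbox[1], b.bbox[1])
    c0 = max(a.bbox[2], b.bbox[2])
    c1 = min(a.bbox[3], b.bbox[3])
    if r1 <= r0 or c1 <= c0:
        return 0.0

    def crop(d: SphereDetection) -> np.ndarray:
        return d.mask[
            r0 - d.bbox[0] : r1 - d.bbox[0], c0 - d.bbox[2] : c1 - d.bbox[2]
        ]

    inter = int((crop(a) & crop(b)).sum())
    union = a.area_px + b.area_px - inter
    return inter / union if union else 0.0


def _merge_duplicates(
    detections: list[SphereDetection], iou_threshold: float = 0.5
) -> list[SphereDetection]:
    """Drop the smaller of any pair of detections with mask IoU > 0.5.

    Such pairs arise when overlapping ROIs segment the same sphere twice.
    """
    keep: list[SphereDetection] = []
    for det in sorted(detections, key=lambda d: -d.area_px):
        if all(_mask_iou(det, k) <= iou_threshold for k in keep):
            keep.append(det)
    return keep


def number_spheres(detections: list[SphereDetection]) -> list[SphereDetection]:
    """Assign labels 1..N in raster order of centroids.

    Centroids are rounded to the nearest integer pixel; ordering is by
    (row, column), ties broken by larger area first.  The rule is
    deterministic and independent of input order, so repeated imaging of
    the same field yields the same numbers.
    """
    ordered = sorted(
        detections,
        key=lambda d: (
            round(d.centroid[0]),
            round(d.centroid[1]),
            -d.area_px,
        ),
    )
    for i, det in enumerate(ordered, start=1):
        det.label = i
    return ordered
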