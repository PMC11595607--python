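"""Seeded synthetic microscopy-image generator with ground truth.

Emulates the two acquisition regimes of sphere-formation assays:

* **uniform** backgrounds, as seen when imaging wells of a 12-multiwell
  plate — flat illumination, mild sensor noise;
* **microfluidic** backgrounds — a circular chamber whose PDMS wall casts a
  dark ring shadow, a radial illumination gradient, and small clusters of
  erythrocyte-like specks that real primary-culture images contain.

Spheres are rendered as phase-contrast-like bright discs with a darker rim
(halo) at the boundary.  Ground-truth masks are the noise-free disc
supports, so every pipeline stage can be validated without real data.
All randomness is driven by the scene seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import GrayImage


@dataclass(frozen=True)
class SphereSpec:
    """One rendered sphere: a bright core with a dark rim inside radius."""

    center: tuple[float, float]  # (row, col)
    radius: float  # px, full support radius
    core_intensity: float = 0.85
    halo_width: float = 2.0  # px, rim band inside the support boundary
    halo_intensity: float = 0.15

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"sphere radius must be > 0, got {self.radius}")
        if self.halo_width < 0 or self.halo_width >= self.radius:
            raise ValueError("halo_width must be in [0, radius)")


@dataclass(frozen=True)
class ChamberSpec:
    """A microfluidic chamber wall: dark ring plus shadow outside it."""

    center: tuple[float, float]
    radius: float
    wall_width: float = 5.0
    shadow_depth: float = 0.25


@dataclass(frozen=True)
class SceneSpec:
    """Full description of a synthetic scene; the seed fixes all randomness."""

    image_size: tuple[int, int] = (320, 320)
    spheres: tuple[SphereSpec, ...] = ()
    background_level: float = 0.45
    #: linear gradient, intensity change per pixel along (row, col)
    background_gradient: tuple[float, float] = (0.0, 0.0)
    #: intensity change from center to corner (radial vignetting)
    background_radial: float = 0.0
    chamber: ChamberSpec | None = None
    n_artifact_clusters: int = 0
    artifact_radius_range: tuple[float, float] = (1.0, 2.0)
    artifact_intensity: float = 0.8
    noise_sigma: float = 0.0
    seed: int = 0
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        h, w = self.image_size
        for s in self.spheres:
            r0, c0 = s.center
            if not (s.radius <= r0 <= h - 1 - s.radius) or not (
                s.radius <= c0 <= w - 1 - s.radius
            ):
                raise ValueError(
                    f"sphere at {s.center} (radius {s.radius}) exceeds "
                    f"image bounds {self.image_size}"
                )
        if not self.allow_overlap:
            for i, a in enumerate(self.spheres):
                for b in self.spheres[i + 1 :]:
                    d = math.hypot(
                        a.center[0] - b.center[0], a.center[1] - b.center[1]
                    )
                    if d < a.radius + b.radius:
                        raise ValueError(
                            "overlapping spheres are not permitted unless "
                            "allow_overlap is set"
                        )


@dataclass
class GroundTruth:
    """Per-sphere noise-free supports plus their exact pixel areas."""

    masks: list[np.ndarray] = field(default_factory=list)
    areas_px: list[int] = field(default_factory=list)
    centers: list[tuple[float, float]] = field(default_factory=list)
    radii: list[float] = field(default_factory=list)

    @property
    def n_spheres(self) -> int:
        return len(self.masks)


def _paint_disc(img: np.ndarray, dist: np.ndarray, radius: float, value: float) -> None:
    # Antialiased paint: per-pixel coverage ramps over a 1-px band.
    coverage = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    img *= 1.0 - coverage
    img += value * coverage


def generate_scene(spec: SceneSpec) -> tuple[GrayImage, GroundTruth]:
    """Render a scene and its ground truth.

    Order of composition: background (level + gradients), chamber shadow,
    spheres (halo disc then bright core), artifact specks, Gaussian noise.
    Ground-truth masks are the discrete supports ``dist <= radius`` before
    noise; their areas are exact pixel counts.
    """
    h, w = spec.image_size
    rng = np.random.default_rng(spec.seed)
    rows, cols = np.mgrid[0:h, 0:w].astype(np.float64)

    img = np.full((h, w), spec.background_level, dtype=np.float64)
    gr, gc = spec.background_gradient
    img += gr * (rows - h / 2) + gc * (cols - w / 2)
    if spec.background_radial != 0.0:
        d_center = np.hypot(rows - h / 2, cols - w / 2)
        img += spec.background_radial * d_center / d_center.max()

    if spec.chamber is not None:
        ch = spec.chamber
        d_ch = np.hypot(rows - ch.center[0], cols - ch.center[1])
        ring = np.abs(d_ch - ch.radius) <= ch.wall_width / 2
        img[ring] -= ch.shadow_depth
        img[d_ch > ch.radius + ch.wall_width / 2] -= ch.shadow_depth / 2

    truth = GroundTruth()
    for s in spec.spheres:
        dist = np.hypot(rows - s.center[0], cols - s.center[1])
        _paint_disc(img, dist, s.radius, s.halo_intensity)
        _paint_disc(img, dist, s.radius - s.halo_width, s.core_intensity)
        mask = dist <= s.radius
        truth.masks.append(mask)
        truth.areas_px.append(int(mask.sum()))
        truth.centers.append(s.center)
        truth.radii.append(s.radius)

    for _ in range(spec.n_artifact_clusters):
        cr = rng.uniform(0.1 * h, 0.9 * h)
        cc = rng.uniform(0.1 * w, 0.9 * w)
        n_specks = rng.integers(3, 7)
        for _ in range(n_specks):
            sr = cr + rng.normal(0, 4.0)
            sc = cc + rng.normal(0, 4.0)
            rad = rng.uniform(*spec.artifact_radius_range)
            dist = np.hypot(rows - sr, cols - sc)
            _paint_disc(img, dist, rad, spec.artifact_intensity)

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)

    np.clip(img, 0.0, 1.0, out=img)
    return GrayImage(pixels=img, source_path=""), truth


def random_scene(
    n_spheres: int,
    seed: int,
    image_size: tuple[int, int] = (320, 320),
    background: str = "uniform",
    radius_range: tuple[float, float] = (10.0, 22.0),
    min_gap_px: float = 8.0,
    noise_sigma: float = 0.02,
    n_artifact_clusters: int | None = None,
) -> SceneSpec:
    """Randomly place non-overlapping spheres and return the scene spec.

    ``background`` is ``"uniform"`` (multiwell-plate regime) or
    ``"microfluidic"`` (chamber wall shadow, radial gradient and
    erythrocyte-like speck clusters).  Placement uses rejection sampling
    driven by ``seed``; spheres keep at least ``min_gap_px`` between their
    boundaries and stay clear of the image border (and of the chamber
    wall, if present).
    """
    if background not in ("uniform", "microfluidic"):
        raise ValueError(f"unknown background regime: {background!r}")
    rng = np.random.default_rng(seed)
    h, w = image_size

    chamber = None
    if background == "microfluidic":
        chamber = ChamberSpec(
            center=(h / 2, w / 2), radius=0.42 * min(h, w), wall_width=5.0,
            shadow_depth=0.25,
        )
        if n_artifact_clusters is None:
            n_artifact_clusters = 3
    if n_artifact_clusters is None:
        n_artifact_clusters = 0

    placed: list[SphereSpec] = []
    attempts = 0
    while len(placed) < n_spheres and attempts < 5000:
        attempts += 1
        radius = rng.uniform(*radius_range)
        margin = radius + 4.0
        cr = rng.uniform(margin, h - 1 - margin)
        cc = rng.uniform(margin, w - 1 - margin)
        if chamber is not None:
            d = math.hypot(cr - chamber.center[0], cc - chamber.center[1])
            if d + radius > chamber.radius - chamber.wall_width / 2 - 3:
                continue
        ok = all(
            math.hypot(cr - p.center[0], cc - p.center[1])
            >= radius + p.radius + min_gap_px
            for p in placed
        )
        if ok:
            placed.append(SphereSpec(center=(cr, cc), radius=radius))
    if len(placed) < n_spheres:
        raise RuntimeError(
            f"could not place {n_spheres} non-overlapping spheres in "
            f"{image_size} after {attempts} attempts"
        )

    spec = SceneSpec(
        image_size=image_size,
        spheres=tuple(placed),
        chamber=chamber,
        background_radial=-0.08 if background == "microfluidic" else 0.0,
        n_artifact_clusters=n_artifact_clusters,
        noise_sigma=noise_sigma,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return spec


def with_noise(spec: SceneSpec, noise_sigma: float) -> SceneSpec:
    """Same scene, different noise level (placement unchanged)."""
    return replace(spec, noise_sigma=noise_sigma)


def score_detections(
    truth: GroundTruth, detections
) -> tuple[float, float, float]:
    """(precision, recall, f1) of detections against ground truth.

    A truth sphere counts as recalled if some detection centroid falls
    inside its support disc; a detection counts as correct if its centroid
    falls inside any truth disc.  Edge cases: empty truth gives recall 1,
    empty detections give precision 1.
    """
    matched_truth = 0
    for center, radius in zip(truth.centers, truth.radii):
        for det in detections:
            dr, dc = det.centroid
            if math.hypot(dr - center[0], dc - center[1]) <= radius:
                matched_truth += 1
                break
    correct_dets = 0
    for det in detections:
        dr, dc = det.centroid
        for center, radius in zip(truth.centers, truth.radii):
            if math.hypot(dr - center[0], dc - center[1]) <= radius:
                correct_dets += 1
                break
    precision = correct_dets / len(detections) if detections else 1.0
    recall = matched_truth / truth.n_spheres if truth.n_spheres else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1
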