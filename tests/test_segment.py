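"""Sobel gradients, Otsu and adaptive thresholds, binary morphology."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spherequant import (
    BinaryMask,
    DegenerateHistogramError,
    adaptive_threshold,
    morph_close_dilate,
    otsu_threshold,
    sobel,
)

from conftest import make_image


# --- independent oracles ----------------------------------------------------


def otsu_brute_force(arr: np.ndarray, n_bins: int = 256) -> float:
    """Exhaustive search over all interior bin edges.

    Recomputes the between-class variance per candidate with explicit
    loops over the histogram; ties broken by the lowest threshold.
    """
    lo, hi = float(arr.min()), float(arr.max())
    hist, edges = np.histogram(arr, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_sigma, best_edge = -1.0, None
    for k in range(n_bins - 1):
        w0 = mu0_mass = 0.0
        for b in range(k + 1):
            w0 += hist[b]
            mu0_mass += hist[b] * centers[b]
        w1 = mu1_mass = 0.0
        for b in range(k + 1, n_bins):
            w1 += hist[b]
            mu1_mass += hist[b] * centers[b]
        if w0 == 0 or w1 == 0:
            continue
        sigma_b = w0 * w1 * (mu0_mass / w0 - mu1_mass / w1) ** 2
        if sigma_b > best_sigma + 1e-12:
            best_sigma, best_edge = sigma_b, edges[k + 1]
    return float(best_edge)


def brute_dilate(mask: np.ndarray, selem: np.ndarray) -> np.ndarray:
    """Set-theoretic dilation: union of shifted copies."""
    h, w = mask.shape
    r = selem.shape[0] // 2
    out = np.zeros_like(mask)
    for dr in range(-r, r + 1):
        for dc in range(-r, r + 1):
            if not selem[dr + r, dc + r]:
                continue
            shifted = np.zeros_like(mask)
            rs0, rs1 = max(0, dr), min(h, h + dr)
            cs0, cs1 = max(0, dc), min(w, w + dc)
            shifted[rs0:rs1, cs0:cs1] = mask[
                max(0, -dr) : h - max(0, dr), max(0, -dc) : w - max(0, dc)
            ]
            out |= shifted
    return out


def brute_erode(mask: np.ndarray, selem: np.ndarray) -> np.ndarray:
    """Erosion as complement of dilation of the complement."""
    return ~brute_dilate(~mask, selem[::-1, ::-1])


# --- sobel ------------------------------------------------------------------


class TestSobel:
    def test_constant_image_has_zero_gradient(self):
        field = sobel(make_image(np.full((12, 12), 0.4)))
        np.testing.assert_allclose(field.G, 0.0, atol=1e-12)

    def test_vertical_step_edge_magnitude_is_four(self):
        px = np.zeros((10, 10))
        px[:, 5:] = 1.0
        field = sobel(make_image(px))
        # the 3x3 kernel sums weights 1+2+1 across the step
        np.testing.assert_allclose(np.abs(field.Gx[3:7, 4:6]), 4.0)
        np.testing.assert_allclose(field.Gy[3:7, 4:6], 0.0, atol=1e-12)
        np.testing.assert_allclose(field.G[3:7, 4:6], 4.0)

    def test_transpose_swaps_gradient_components(self, rng):
        # Gy is the transpose kernel of Gx, so transposing the image swaps
        # the roles (equal to machine precision; summation order differs)
        px = rng.uniform(0, 1, size=(16, 16))
        f = sobel(make_image(px))
        ft = sobel(make_image(px.T))
        np.testing.assert_allclose(ft.Gx, f.Gy.T, atol=1e-12)
        np.testing.assert_allclose(ft.Gy, f.Gx.T, atol=1e-12)

    def test_magnitude_invariant_to_constant_shift(self, rng):
        px = rng.uniform(0, 0.5, size=(16, 16))
        f1 = sobel(make_image(px))
        f2 = sobel(make_image(px + 0.3))
        np.testing.assert_allclose(f1.G, f2.G, atol=1e-12)

    def test_magnitude_and_direction_consistent(self, rng):
        px = rng.uniform(0, 1, size=(12, 12))
        f = sobel(make_image(px))
        np.testing.assert_allclose(f.G, np.hypot(f.Gx, f.Gy))
        np.testing.assert_allclose(f.theta, np.arctan2(f.Gy, f.Gx))

    def test_rejects_too_small_image(self):
        with pytest.raises(ValueError):
            sobel(np.zeros((2, 5)))


# --- otsu -------------------------------------------------------------------


class TestOtsuThreshold:
    def test_bimodal_image_separated_exactly(self):
        px = np.full((10, 10), 0.2)
        px[:, 6:] = 0.8
        t = otsu_threshold(make_image(px))
        assert 0.2 < t < 0.8
        assert np.array_equal(px > t, px == 0.8)

    def test_matches_brute_force_on_random_8_level_images(self, rng):
        for _ in range(200):
            levels = rng.uniform(0, 1, size=8)
            px = rng.choice(levels, size=(12, 12))
            if np.ptp(px) < 1e-12:
                continue
            assert otsu_threshold(px, n_bins=8) == pytest.approx(
                otsu_brute_force(px, n_bins=8), abs=1e-12
            )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.integers(min_value=0, max_value=7), min_size=16, max_size=64
        )
    )
    def test_matches_brute_force_on_arbitrary_level_patterns(self, data):
        arr = np.asarray(data, dtype=float).reshape(1, -1) / 7.0
        if np.ptp(arr) < 1e-12:
            return
        assert otsu_threshold(arr, n_bins=8) == pytest.approx(
            otsu_brute_force(arr, n_bins=8), abs=1e-12
        )

    def test_translation_equivariance(self, rng):
        px = rng.uniform(0.1, 0.5, size=(12, 12))
        c = 0.3
        assert otsu_threshold(px + c) == pytest.approx(
            otsu_threshold(px) + c, abs=1e-12
        )

    def test_constant_image_raises_degenerate(self):
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(np.full((8, 8), 0.5))


# --- adaptive threshold -----------------------------------------------------


class TestAdaptiveThreshold:
    def test_constant_image_positive_offset_all_foreground(self):
        # every pixel equals its local mean, so x > x - offset holds
        mask = adaptive_threshold(np.full((12, 12), 0.5), 5, offset=0.1)
        assert mask.foreground_count == 144

    def test_constant_image_negative_offset_all_background(self):
        mask = adaptive_threshold(np.full((12, 12), 0.5), 5, offset=-0.1)
        assert mask.foreground_count == 0

    def test_bright_disk_on_dark_field_recovered(self):
        h = w = 64
        rows, cols = np.mgrid[0:h, 0:w]
        disk = np.hypot(rows - 32, cols - 32) <= 10
        px = np.where(disk, 0.9, 0.1)
        mask = adaptive_threshold(px, 63, offset=0.02)
        core = np.hypot(rows - 32, cols - 32) <= 8.5
        outside = np.hypot(rows - 32, cols - 32) >= 11.5
        assert mask.pixels[core].all()
        assert not mask.pixels[outside].any()

    def test_rejects_even_block_size(self):
        with pytest.raises(ValueError):
            adaptive_threshold(np.zeros((8, 8)), 4, offset=0.0)


# --- morphology -------------------------------------------------------------


class TestMorphCloseDilate:
    def test_empty_mask_passes_through(self):
        out = morph_close_dilate(BinaryMask(np.zeros((10, 10), bool)), 2)
        assert out.foreground_count == 0

    def test_full_mask_saturates(self):
        out = morph_close_dilate(BinaryMask(np.ones((10, 10), bool)), 2)
        assert out.foreground_count == 100

    def test_hole_filled_and_boundary_grown_matches_set_oracle(self):
        from skimage.morphology import disk

        rows, cols = np.mgrid[0:32, 0:32]
        d = np.hypot(rows - 16, cols - 16)
        mask = (d <= 5) & (d > 0.5)  # 10-px disk with a 1-px center hole
        selem = disk(2).astype(bool)
        expected = brute_dilate(
            brute_erode(brute_dilate(mask, selem), selem), selem
        )
        out = morph_close_dilate(BinaryMask(mask), 2)
        assert (d <= 0.5).sum() == 1 and out.pixels[16, 16]  # hole filled
        np.testing.assert_array_equal(out.pixels, expected)

    def test_extensive_and_increasing_on_random_masks(self, rng):
        for _ in range(10):
            a = rng.random((24, 24)) < 0.2
            b = a | (rng.random((24, 24)) < 0.1)
            fa = morph_close_dilate(BinaryMask(a), 2).pixels
            fb = morph_close_dilate(BinaryMask(b), 2).pixels
            assert (a <= fa).all()  # extensive: A subset of f(A)
            assert (fa <= fb).all()  # increasing: A subset of B -> f(A) subset of f(B)

    def test_rejects_radius_below_one(self):
        with pytest.raises(ValueError):
            morph_close_dilate(BinaryMask(np.zeros((4, 4), bool)), 0)
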