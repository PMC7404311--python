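"""Segmentation primitives against brute-force oracles and scaling invariants."""

import numpy as np
import pytest

from micromorph.imageops import (
    edge_cell_mask,
    label_and_measure,
    rolling_ball_subtract,
    threshold_mask,
)


def ball_opening_oracle(img: np.ndarray, r: int) -> np.ndarray:
    """Brute-force grayscale opening with a spherical structuring element."""
    offs = [
        (dy, dx)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if dy * dy + dx * dx <= r * r
    ]
    n = img.shape[0]
    pad = np.pad(img, r, mode="edge")
    ero = np.full_like(img, np.inf)
    for dy, dx in offs:
        h = np.sqrt(r * r - dy * dy - dx * dx)
        ero = np.minimum(ero, pad[r + dy : r + dy + n, r + dx : r + dx + n] - h)
    epad = np.pad(ero, r, mode="edge")
    dil = np.full_like(img, -np.inf)
    for dy, dx in offs:
        h = np.sqrt(r * r - dy * dy - dx * dx)
        dil = np.maximum(dil, epad[r + dy : r + dy + n, r + dx : r + dx + n] + h)
    return dil


def otsu_oracle(values: np.ndarray) -> float:
    """Exhaustive between-class-variance maximisation over all candidate splits."""
    vals = np.sort(values.ravel())
    candidates = np.unique(vals)
    best_t, best_v = candidates[0], -np.inf
    for i in range(len(candidates) - 1):
        t = (candidates[i] + candidates[i + 1]) / 2
        lo, hi = vals[vals <= t], vals[vals > t]
        w0, w1 = len(lo) / len(vals), len(hi) / len(vals)
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


def flood_fill_count(mask: np.ndarray) -> int:
    """8-connectivity component count by explicit stack-based flood fill."""
    mask = mask.copy()
    count = 0
    for start in zip(*np.nonzero(mask)):
        if not mask[start]:
            continue
        count += 1
        stack = [start]
        mask[start] = False
        while stack:
            y, x = stack.pop()
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < mask.shape[0] and 0 <= nx < mask.shape[1] and mask[ny, nx]:
                        mask[ny, nx] = False
                        stack.append((ny, nx))
    return count


class TestRollingBall:
    def test_flat_background_fully_removed(self):
        out = rolling_ball_subtract(np.full((64, 64), 37.0), 8.0, 1.0)
        assert out.max() == 0.0

    def test_small_spot_amplitude_preserved(self):
        img = np.full((64, 64), 10.0)
        img[30:33, 30:33] += 50.0
        out = rolling_ball_subtract(img, 8.0, 1.0, fast=False)
        assert out.max() == pytest.approx(50.0, rel=0.05)

    def test_matches_ball_opening_oracle_on_ramp_with_spots(self):
        X, Y = np.meshgrid(np.arange(64), np.arange(64))
        img = 20 + 0.5 * X + 0.2 * Y
        for cx, cy in [(20, 20), (40, 30), (10, 50)]:
            img += 60 * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / 4)
        expected = np.clip(img - ball_opening_oracle(img, 8), 0, None)
        out = rolling_ball_subtract(img, 8.0, 1.0, fast=False)
        assert np.abs(out - expected).max() <= 1.0

    def test_subpixel_radius_rejected(self):
        with pytest.raises(ValueError, match="below 1 px"):
            rolling_ball_subtract(np.zeros((8, 8)), radius_um=0.05, pixel_size=0.1)


class TestThresholdMask:
    def test_otsu_recovers_bright_class_of_bimodal_image(self, rng):
        truth = rng.random((128, 128)) < 0.4
        img = np.where(truth, rng.normal(100, 8, truth.shape), rng.normal(10, 8, truth.shape))
        mask = threshold_mask(img, "otsu")
        assert (mask == truth).mean() >= 0.99

    def test_otsu_equals_exhaustive_sweep_oracle(self, rng):
        img = rng.integers(0, 256, (40, 40)).astype(float)
        t_oracle = otsu_oracle(img)
        mask = threshold_mask(img, "otsu")
        assert np.array_equal(mask, img > t_oracle)

    def test_fixed_threshold(self):
        img = np.array([[40.0, 60.0], [60.0, 40.0]])
        assert np.array_equal(threshold_mask(img, 50.0), img == 60.0)

    def test_roi_excluding_bright_pixels_gives_empty_mask(self):
        img = np.zeros((10, 10))
        img[:5] = 100.0
        roi = np.zeros_like(img, dtype=bool)
        roi[6:, :] = True
        assert not threshold_mask(img, 50.0, roi=roi).any()

    def test_constant_image_otsu_raises(self):
        with pytest.raises(ValueError, match="fixed threshold"):
            threshold_mask(np.full((8, 8), 5.0), "otsu")

    def test_empty_roi_raises(self):
        with pytest.raises(ValueError, match="empty ROI"):
            threshold_mask(np.zeros((4, 4)), "otsu", roi=np.zeros((4, 4), dtype=bool))


class TestEdgeCellMask:
    def test_disc_area_within_five_percent(self):
        from micromorph.synthetic_data import make_single_cell

        # 700 µm² pattern, round cell of ~630 µm² (radius ≈ 14.2 µm)
        img, truth = make_single_cell(seed=2, circ=1.0, snr=10)
        mask = edge_cell_mask(img.max_project("vinculin").astype(float), img.pixel_size)
        area = mask.sum() * img.pixel_size**2
        assert area == pytest.approx(truth.cell["area_um2"], rel=0.05)

    def test_blank_noise_gives_no_cell(self, rng):
        img = rng.normal(100, 3, (256, 256)).clip(0)
        assert edge_cell_mask(img, 0.1) is None

    def test_two_cells_keeps_largest(self):
        from micromorph.synthetic_data import ellipse_mask

        big = ellipse_mask((256, 256), (-6, 0), (5, 5), 0, 0.1)
        small = ellipse_mask((256, 256), (8, 0), (2.5, 2.5), 0, 0.1)
        img = 100.0 + 50.0 * (big | small)
        mask = edge_cell_mask(img, 0.1, min_cell_area_um2=10.0)
        assert mask is not None
        assert (mask & big).sum() > 0.8 * big.sum()
        assert (mask & small).sum() == 0


class TestLabelAndMeasure:
    def test_min_area_filter(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[2:4, 2:4] = True  # 4 px = 0.04 µm² at 0.1 µm/px → filtered
        mask[10:20, 10:15] = True  # 50 px = 0.5 µm²
        mask[30:50, 30:40] = True  # 200 px = 2.0 µm²
        regions = label_and_measure(mask, 0.1, min_area_um2=0.1)
        assert regions.n_regions == 2
        assert sorted(regions.table["area_um2"]) == pytest.approx([0.5, 2.0])

    def test_area_calibration(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[5:15, 5:15] = True  # 100 px
        regions = label_and_measure(mask, 0.1)
        assert regions.table["area_um2"].iloc[0] == pytest.approx(1.0)

    def test_component_count_equals_flood_fill_oracle(self, rng):
        for _ in range(5):
            mask = rng.random((48, 48)) < 0.25
            regions = label_and_measure(mask, 1.0)
            assert regions.n_regions == flood_fill_count(mask)

    def test_empty_mask(self):
        regions = label_and_measure(np.zeros((8, 8), dtype=bool), 0.1)
        assert regions.n_regions == 0

    def test_region_areas_sum_to_mask_area_without_filter(self, rng):
        mask = rng.random((48, 48)) < 0.3
        regions = label_and_measure(mask, 0.1, min_area_um2=0.0)
        assert regions.total_area_um2 == pytest.approx(mask.sum() * 0.01)

    def test_measurements_scale_with_pixel_size(self):
        """Halving µm/px at doubled resolution leaves µm-unit outputs within 2%."""
        from skimage.transform import resize

        mask = np.zeros((64, 64), dtype=bool)
        mask[20:36, 24:44] = True
        fine = resize(mask.astype(float), (128, 128), order=0) > 0.5
        a = label_and_measure(mask, 0.2).table.iloc[0]
        b = label_and_measure(fine, 0.1).table.iloc[0]
        for col in ("area_um2", "major_axis_um", "minor_axis_um"):
            assert a[col] == pytest.approx(b[col], rel=0.02)
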