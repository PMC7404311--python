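"""Polarity vectors, mirror folding and circular statistics."""

import numpy as np
import pytest

from micromorph.centrosome_polarity import (
    circ_mean_deg,
    circ_median_deg,
    circular_anova,
    detect_polarity,
    fold_mirror,
    summarize_angles,
    _common_median_counts,
    _fisher_P,
)
from micromorph.synthetic_data import make_single_cell


class TestFoldMirror:
    @pytest.mark.parametrize(
        "angle,folded", [(135.0, 45.0), (-135.0, -45.0), (30.0, 30.0), (90.0, 90.0), (180.0, 0.0)]
    )
    def test_examples(self, angle, folded):
        assert fold_mirror([angle])[0] == pytest.approx(folded)

    def test_involution_on_folded_domain(self, rng):
        a = rng.uniform(-90, 90, 200)
        assert np.allclose(fold_mirror(a), a)

    def test_preserves_distance_to_symmetry_axis(self, rng):
        a = rng.uniform(-180, 180, 200)
        # |angle - 90| distance to the front-rear axis, on the circle
        d_before = np.abs(np.angle(np.exp(1j * np.deg2rad(a - 90))))
        d_after = np.abs(np.angle(np.exp(1j * np.deg2rad(fold_mirror(a) - 90))))
        assert np.allclose(d_before, d_after)


class TestCircularMoments:
    def test_identical_vectors_give_R_one(self):
        m, r = circ_mean_deg(np.full(50, 37.0))
        assert r == pytest.approx(1.0)
        assert m == pytest.approx(37.0)

    def test_uniform_grid_gives_R_zero(self):
        _, r = circ_mean_deg(np.arange(0, 360, 1.0))
        assert r == pytest.approx(0.0, abs=1e-10)

    def test_rotation_equivariance(self, rng):
        a = np.degrees(rng.vonmises(0.5, 3, 200))
        m0, r0 = circ_mean_deg(a)
        m1, r1 = circ_mean_deg(a + 123.0)
        assert r1 == pytest.approx(r0)
        assert np.angle(np.exp(1j * np.deg2rad(m1 - m0 - 123.0))) == pytest.approx(0.0, abs=1e-9)

    def test_von_mises_moment_recovery(self, rng):
        from scipy.special import iv

        a = np.degrees(rng.vonmises(np.pi / 2, 2, 300))
        m, r = circ_mean_deg(a)
        assert m == pytest.approx(90.0, abs=5.0)
        assert r == pytest.approx(iv(1, 2) / iv(0, 2), abs=0.05)

    def test_mean_undefined_flag(self):
        s = summarize_angles(np.array([0.0, 90.0, 180.0, 270.0]))
        assert s.mean_undefined
        assert np.isnan(s.mean_angle)

    def test_median_splits_sample_evenly(self, rng):
        a = np.degrees(rng.vonmises(1.0, 2, 101))
        med = circ_median_deg(a)
        d = np.angle(np.exp(1j * np.deg2rad(a - med)))
        assert abs((d > 0).sum() - (d < 0).sum()) <= 1


class TestCircularAnova:
    def test_statistic_matches_hand_evaluation(self):
        """On a fixed n=12 sample the statistic equals the count formula."""
        g1 = np.array([10.0, 20.0, 35.0, 80.0, 95.0, 170.0])
        g2 = np.array([-10.0, -40.0, -60.0, -90.0, 15.0, 25.0])
        out = circular_anova([g1, g2], min_n=6)
        med, n, m = _common_median_counts([g1, g2])
        N, M = n.sum(), m.sum()
        expected = N**2 / (M * (N - M)) * (m[0] ** 2 / n[0] + m[1] ** 2 / n[1]) - N * M / (N - M)
        assert out["statistic"] == pytest.approx(expected)
        assert out["df"] == 1

    def test_separated_groups_detected(self, rng):
        g1 = np.degrees(rng.vonmises(0, 2, 100))
        g2 = np.degrees(rng.vonmises(np.pi / 2, 2, 100))
        assert circular_anova([g1, g2])["pvalue"] < 0.01

    def test_same_distribution_not_detected_typically(self, rng):
        ps = []
        for _ in range(20):
            g1 = np.degrees(rng.vonmises(0, 2, 50))
            g2 = np.degrees(rng.vonmises(0, 2, 50))
            ps.append(circular_anova([g1, g2])["pvalue"])
        assert np.median(ps) > 0.2

    def test_three_groups_supported(self, rng):
        gs = [np.degrees(rng.vonmises(0, 2, 40)) for _ in range(3)]
        out = circular_anova(gs)
        assert out["df"] == 2
        assert 0 <= out["pvalue"] <= 1

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 10"):
            circular_anova([np.zeros(5), np.zeros(20)])

    def test_degenerate_identical_angles(self):
        with pytest.raises(ValueError, match="degenerate"):
            circular_anova([np.full(20, 10.0), np.full(20, 10.0)])


class TestDetectPolarity:
    def test_front_pointing_centrosome_near_90deg(self, crossbow_cfg):
        img, _ = make_single_cell(
            pattern="crossbow1100", centrosome_angle_deg=90, centrosome_offset_um=5, seed=21
        )
        rec = detect_polarity(img, crossbow_cfg)
        assert rec.included
        assert rec.angle == pytest.approx(90.0, abs=3.0)
        assert np.hypot(*rec.vector) == pytest.approx(5.0, abs=0.5)

    def test_rotated_scene_same_pattern_frame_angle(self, crossbow_cfg):
        for orient in (50.0, 200.0):
            img, _ = make_single_cell(
                pattern="crossbow1100",
                centrosome_angle_deg=-120,
                orientation_deg=orient,
                seed=22,
            )
            rec = detect_polarity(img, crossbow_cfg)
            assert rec.angle == pytest.approx(-120.0, abs=4.0)

    def test_coincident_centrosome_flagged_undefined(self, crossbow_cfg):
        img, _ = make_single_cell(
            pattern="crossbow1100", centrosome_offset_um=0.0, seed=23
        )
        rec = detect_polarity(img, crossbow_cfg)
        assert not rec.included
        assert np.isnan(rec.angle)
        assert "undefined" in rec.flag

    def test_missing_channel_raises(self, crossbow_cfg):
        from micromorph.io_core import CalibratedImage

        img, _ = make_single_cell(pattern="crossbow1100", seed=24)
        bare = CalibratedImage(img.pixels, img.pixel_size, {"pattern": 0, "nucleus": 3})
        with pytest.raises(KeyError, match="centrosome"):
            detect_polarity(bare, crossbow_cfg)
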