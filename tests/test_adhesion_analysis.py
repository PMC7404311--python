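"""Adhesion quantification: circularity, exclusion rules, recovery, group stats."""

import numpy as np
import pandas as pd
import pytest

from micromorph.adhesion_analysis import (
    analyze_cell,
    circularity_index,
    compare_conditions,
    results_table,
)
from micromorph.io_core import AssayConfig
from micromorph.synthetic_data import ellipse_mask, make_single_cell


class TestCircularityIndex:
    def test_perfect_disc_is_one(self):
        disc = ellipse_mask((512, 512), (0, 0), (15, 15), 0, 0.1)
        assert circularity_index(disc) == pytest.approx(1.0, abs=0.02)

    @pytest.mark.parametrize("angle", [0, 30, 75])
    def test_two_to_one_ellipse_is_half(self, angle):
        ell = ellipse_mask((512, 512), (0, 0), (10, 5), angle, 0.1)
        assert circularity_index(ell) == pytest.approx(0.5, abs=0.02)

    def test_fifty_percent_longer_than_wide_bound(self):
        """Cells 50% longer than wide score at most 1/1.5."""
        ell = ellipse_mask((512, 512), (0, 0), (12, 8), 10, 0.1)
        assert circularity_index(ell) <= 0.667 + 0.02

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            circularity_index(np.zeros((8, 8), dtype=bool))


class TestAnalyzeCell:
    def test_recovers_planted_sites(self, single_cell_scene, disc700_cfg):
        img, truth = single_cell_scene
        res = analyze_cell(img, disc700_cfg)
        true_sites = [s for s in truth.sites if s["area_um2"] >= 0.1]
        true_area = sum(s["area_um2"] for s in true_sites)
        assert abs(res.n_adhesions - len(true_sites)) <= 2
        assert res.total_adhesion_area == pytest.approx(true_area, rel=0.10)
        assert not res.excluded

    def test_sub_threshold_sites_not_counted(self, disc700_cfg):
        areas = [0.04] * 5 + list(np.linspace(0.2, 2.0, 30))
        img, truth = make_single_cell(seed=501, site_areas=areas, snr=10)
        res = analyze_cell(img, disc700_cfg)
        assert sum(1 for s in truth.sites if s["area_um2"] >= 0.1) == 30
        assert res.n_adhesions == 30
        assert (res.sites["area_um2"] >= disc700_cfg.min_adhesion_area).all()

    def test_small_cell_on_crossbow_excluded(self, crossbow_cfg):
        img, _ = make_single_cell(
            pattern="crossbow1100", cell_area=300, circ=0.9, n_sites=10, seed=9
        )
        res = analyze_cell(img, crossbow_cfg)
        assert res.excluded
        assert "400" in res.exclusion_reason or "cover" in res.exclusion_reason

    def test_cover_fraction_exclusion(self):
        # 450 µm² cell passes the absolute floor but covers < 1/3 of 1600 µm²
        cfg = AssayConfig(pattern_area=1600.0)
        img, _ = make_single_cell(pattern="disc1600", cell_area=450, circ=0.9, n_sites=10, seed=13)
        res = analyze_cell(img, cfg)
        assert res.excluded
        assert "cover" in res.exclusion_reason

    def test_relative_area_identity(self, single_cell_scene, disc700_cfg):
        img, _ = single_cell_scene
        res = analyze_cell(img, disc700_cfg)
        assert res.relative_adhesion_area == pytest.approx(
            100 * res.total_adhesion_area / res.cell_area
        )
        assert res.n_adhesions == len(res.sites)

    def test_invariant_under_uniform_intensity_rescaling(self, single_cell_scene, disc700_cfg):
        from micromorph.io_core import CalibratedImage

        img, _ = single_cell_scene
        res1 = analyze_cell(img, disc700_cfg)
        scaled = CalibratedImage(
            img.pixels.astype(np.float64) * 2.0, img.pixel_size, img.channels, img.z_step
        )
        res2 = analyze_cell(scaled, disc700_cfg)
        assert res2.relative_adhesion_area == pytest.approx(res1.relative_adhesion_area, rel=0.02)

    def test_missing_channel_raises(self, single_cell_scene, disc700_cfg):
        from micromorph.io_core import CalibratedImage

        img, _ = single_cell_scene
        bare = CalibratedImage(img.pixels, img.pixel_size, {"nucleus": 3})
        with pytest.raises(KeyError, match="vinculin"):
            analyze_cell(bare, disc700_cfg)


def _mock_table(rng, n, cond, pattern_area, mean_area=600.0):
    return pd.DataFrame(
        {
            "condition": cond,
            "pattern_area_um2": pattern_area,
            "cell_area_um2": rng.normal(mean_area, 60, n),
            "circularity": rng.uniform(0.7, 1.0, n),
            "n_adhesions": rng.integers(20, 40, n),
            "total_adh_area_um2": rng.normal(30, 5, n),
            "rel_adh_area_pct": rng.normal(5, 1, n),
            "excluded": False,
        }
    )


class TestCompareConditions:
    def test_identical_duplicated_group_zero_change(self, rng):
        a = _mock_table(rng, 20, "ctrl", 700.0)
        b = a.copy()
        b["condition"] = "si"
        out = compare_conditions(pd.concat([a, b]), metrics=("cell_area_um2",))
        pct = out["pct_change_vs_reference"]["cell_area_um2"]
        assert np.allclose(pct.to_numpy(), 0.0)

    def test_two_way_anova_detects_planted_difference(self, rng):
        tables = []
        for cond, pa, mean in [
            ("ctrl", 700.0, 530.0),
            ("ctrl", 1600.0, 700.0),
            ("si", 700.0, 530.0),
            ("si", 1600.0, 700.0),
        ]:
            tables.append(_mock_table(rng, 100, cond, pa, mean_area=mean))
        out = compare_conditions(pd.concat(tables), metrics=("cell_area_um2",))
        anova = out["anova"]["cell_area_um2"]
        p_conf = anova.loc["C(pattern_area_um2)", "PR(>F)"]
        assert p_conf < 1e-6
        # direction: 1600 µm² group mean larger
        summ = out["summary"]["cell_area_um2"]["mean"]
        assert summ.xs(1600.0, level=1).mean() > summ.xs(700.0, level=1).mean()

    def test_type_one_error_rate_near_nominal(self, rng):
        """Same-distribution groups reject at ~alpha under the two-way ANOVA."""
        from statsmodels.formula.api import ols
        from statsmodels.stats.anova import anova_lm

        rej = 0
        n_sim = 400
        for _ in range(n_sim):
            d = pd.DataFrame(
                {
                    "y": rng.normal(0, 1, 40),
                    "condition": ["a"] * 10 + ["b"] * 10 + ["a"] * 10 + ["b"] * 10,
                    "pattern_area_um2": [700.0] * 20 + [1600.0] * 20,
                }
            )
            a = anova_lm(ols("y ~ C(condition) * C(pattern_area_um2)", data=d).fit(), typ=2)
            rej += a.loc["C(condition)", "PR(>F)"] < 0.05
        assert 0.02 <= rej / n_sim <= 0.08

    def test_single_group_rejected(self, rng):
        with pytest.raises(ValueError, match="two"):
            compare_conditions(_mock_table(rng, 10, "ctrl", 700.0))

    def test_results_table_layout(self, single_cell_scene, disc700_cfg):
        img, _ = single_cell_scene
        df = results_table([analyze_cell(img, disc700_cfg, condition="ctrl")])
        assert list(df.columns) == [
            "condition",
            "pattern_area_um2",
            "cell_area_um2",
            "circularity",
            "n_adhesions",
            "total_adh_area_um2",
            "rel_adh_area_pct",
            "excluded",
            "exclusion_reason",
        ]
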