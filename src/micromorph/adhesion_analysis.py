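"""Per-cell steady-state adhesion quantification on disc micropatterns.

The pipeline per field: whole-cell mask by edge detection on the vinculin
stain → rolling-ball background subtraction within the ROI → intensity
threshold → connected adhesion sites ≥ 0.1 µm² → per-cell metrics (spreading
area, circularity, adhesion count, total and relative adhesion area).

Cells below 400 µm² or covering less than a third of the pattern area are
excluded (returned with ``excluded=True`` and a reason, never dropped
silently).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage import measure

from micromorph.io_core import AssayConfig, CalibratedImage
from micromorph.imageops import (
    LabeledRegions,
    edge_cell_mask,
    label_and_measure,
    otsu_threshold,
    rolling_ball_subtract,
    threshold_mask,
)


@dataclass
class AdhesionResult:
    """Adhesion metrics of one cell.

    ``relative_adhesion_area`` is the percentage of the cell spreading area
    occupied by adhesion sites (total site area / cell area × 100).
    """

    cell_area: float  # µm²
    circularity: float
    n_adhesions: int
    total_adhesion_area: float  # µm²
    relative_adhesion_area: float  # %
    sites: pd.DataFrame  # per-site area, centroid, mean vinculin intensity
    pattern_area: float  # µm²
    condition: str = ""
    excluded: bool = False
    exclusion_reason: str = ""

    def to_row(self) -> dict:
        return {
            "condition": self.condition,
            "pattern_area_um2": self.pattern_area,
            "cell_area_um2": self.cell_area,
            "circularity": self.circularity,
            "n_adhesions": self.n_adhesions,
            "total_adh_area_um2": self.total_adhesion_area,
            "rel_adh_area_pct": self.relative_adhesion_area,
            "excluded": self.excluded,
            "exclusion_reason": self.exclusion_reason,
        }


def circularity_index(cell_mask: np.ndarray) -> float:
    """Cell-shape circularity: minor-to-major axis ratio of the best-fit ellipse.

    1 for a round cell, smaller for elongated cells; a cell 50% longer than
    wide scores 1/1.5 ≈ 0.67.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("empty cell mask")
    props = measure.regionprops(cell_mask.astype(np.uint8))[0]
    major = props.axis_major_length
    minor = props.axis_minor_length
    if major == 0:
        raise ValueError("degenerate cell mask (single pixel?)")
    return float(min(minor / major, 1.0))


def analyze_cell(
    img: CalibratedImage,
    cfg: AssayConfig,
    condition: str = "",
    mask_channel: str = "vinculin",
) -> AdhesionResult:
    """Quantify adhesion sites of a single micropatterned cell.

    Raises ``ValueError`` when no cell is found; returns an excluded record
    (metrics still filled in) when the cell fails the size or pattern-cover
    criteria.
    """
    img.require_roles(["vinculin"])
    px = img.pixel_size
    vinculin = img.max_project("vinculin").astype(float)
    mask_img = img.max_project(mask_channel).astype(float)

    cell_mask = edge_cell_mask(mask_img, px, min_cell_area_um2=50.0)
    if cell_mask is None:
        raise ValueError("no cell found in field")
    cell_area = float(cell_mask.sum() * px**2)
    circ = circularity_index(cell_mask)

    corrected = rolling_ball_subtract(vinculin, cfg.rolling_ball_radius, px)
    # mild denoise before thresholding; tiny puncta are preserved at sigma ~1 px
    smoothed = ndi.gaussian_filter(corrected, max(0.1 / px, 1.0))
    method = cfg.threshold_method
    if method == "otsu":
        # Otsu can collapse into the noise when sites occupy a vanishing
        # fraction of the ROI; floor it at a robust background quantile.
        vals = smoothed[cell_mask]
        med = float(np.median(vals))
        mad = float(np.median(np.abs(vals - med))) * 1.4826
        method = max(otsu_threshold(vals), med + 3.5 * mad)
    site_mask = threshold_mask(smoothed, method, roi=cell_mask)
    regions: LabeledRegions = label_and_measure(
        site_mask, px, min_area_um2=cfg.min_adhesion_area, intensity_image=vinculin
    )

    total = regions.total_area_um2
    result = AdhesionResult(
        cell_area=cell_area,
        circularity=circ,
        n_adhesions=regions.n_regions,
        total_adhesion_area=total,
        relative_adhesion_area=100.0 * total / cell_area,
        sites=regions.table,
        pattern_area=cfg.pattern_area,
        condition=condition,
    )
    if cell_area < cfg.min_cell_area:
        result.excluded = True
        result.exclusion_reason = f"cell_area {cell_area:.0f} µm² < {cfg.min_cell_area:.0f} µm²"
    elif cell_area < cfg.min_pattern_cover_fraction * cfg.pattern_area:
        result.excluded = True
        result.exclusion_reason = (
            f"cell covers {cell_area / cfg.pattern_area:.2f} of pattern "
            f"< {cfg.min_pattern_cover_fraction:.2f}"
        )
    return result


def results_table(results: list[AdhesionResult]) -> pd.DataFrame:
    """Stack per-cell results into the exported table layout."""
    return pd.DataFrame([r.to_row() for r in results])


METRICS = ("cell_area_um2", "circularity", "n_adhesions", "total_adh_area_um2", "rel_adh_area_pct")


def compare_conditions(
    table: pd.DataFrame,
    metrics: tuple[str, ...] = METRICS,
    reference: tuple[str, float] | None = None,
) -> dict:
    """Group summaries and two-way ANOVA (treatment × confinement) with Tukey post hoc.

    ``table`` must contain ``condition`` (treatment label) and
    ``pattern_area_um2`` (confinement level) plus the metric columns; excluded
    cells are ignored.  Returns ``{"summary": DataFrame, "anova": {metric:
    DataFrame}, "tukey": {metric: DataFrame}}``.  Effect direction is reported
    as percent change of the group mean versus the reference group (first
    group by default).
    """
    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = table.loc[~table.get("excluded", False).astype(bool)].copy()
    groups = df.groupby(["condition", "pattern_area_um2"])
    if groups.ngroups < 2:
        raise ValueError("need at least two (treatment, confinement) groups")
    if (groups.size() < 3).any():
        raise ValueError("each group needs n >= 3")

    summary = groups[list(metrics)].agg(["mean", "median", "std", "count"])
    ref_key = reference if reference is not None else sorted(groups.groups)[0]

    anova_out: dict[str, pd.DataFrame] = {}
    tukey_out: dict[str, pd.DataFrame] = {}
    pct_change = {}
    for m in metrics:
        ref_mean = groups[m].mean().loc[ref_key]
        pct_change[m] = (groups[m].mean() - ref_mean) / ref_mean * 100.0 if ref_mean else np.nan
        d = df.rename(columns={m: "y"})[["y", "condition", "pattern_area_um2"]].dropna()
        if d["y"].nunique() > 1 and d["condition"].nunique() > 1 and d["pattern_area_um2"].nunique() > 1:
            model = ols("y ~ C(condition) * C(pattern_area_um2)", data=d).fit()
            anova_out[m] = anova_lm(model, typ=2)
        elif d["y"].nunique() > 1:
            # single factor present: one-way layout
            model = ols("y ~ C(condition)" if d["condition"].nunique() > 1 else "y ~ C(pattern_area_um2)", data=d).fit()
            anova_out[m] = anova_lm(model, typ=2)
        combined = d["condition"].astype(str) + "|" + d["pattern_area_um2"].astype(str)
        if d["y"].nunique() > 1 and combined.nunique() > 1:
            tk = pairwise_tukeyhsd(d["y"].to_numpy(), combined.to_numpy())
            tukey_out[m] = pd.DataFrame(
                tk.summary().data[1:], columns=tk.summary().data[0]
            )
    return {
        "summary": summary,
        "pct_change_vs_reference": pd.DataFrame(pct_change),
        "reference_group": ref_key,
        "anova": anova_out,
        "tukey": tukey_out,
    }
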