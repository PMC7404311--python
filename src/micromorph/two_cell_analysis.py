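"""Two-cell-stage centrosome positioning: the nuclear/centrosomal distance ratio.

In a cell pair, centrally positioned centrosomes (near the cell-cell
interface) give a large internuclear-to-intercentrosomal distance ratio
d_nn/d_cc, while peripheral centrosomes give a small one.  The ratio is
invariant under translation, rotation and uniform scaling, so no further
normalisation is needed; d_nn and d_cc are additionally exported normalised by
the pattern diameter for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy import stats
from scipy.optimize import linear_sum_assignment

from micromorph.io_core import AssayConfig, CalibratedImage
from micromorph.imageops import threshold_mask
from micromorph.centrosome_polarity import _centroid_xy, _detect_puncta

MIN_DCC_UM = 0.2  # coincident centrosomes: ratio numerically unstable


@dataclass
class TwoCellRecord:
    """Paired nucleus/centrosome geometry of one two-cell stage (µm)."""

    nucleus_1: tuple[float, float]
    nucleus_2: tuple[float, float]
    centrosome_1: tuple[float, float]
    centrosome_2: tuple[float, float]
    d_nn: float
    d_cc: float
    ratio: float
    pattern_area: float
    flag: str = ""

    def to_row(self) -> dict:
        diameter = 2 * np.sqrt(self.pattern_area / np.pi)
        return {
            "d_nn_um": self.d_nn,
            "d_cc_um": self.d_cc,
            "ratio": self.ratio,
            "d_nn_norm": self.d_nn / diameter,
            "d_cc_norm": self.d_cc / diameter,
            "pattern_area_um2": self.pattern_area,
            "flags": self.flag,
        }


def ratio_from_points(
    nuclei: np.ndarray,
    centrosomes: np.ndarray,
) -> float:
    """d_nn/d_cc from two nucleus and two centrosome positions (any 2D frame)."""
    nuclei = np.asarray(nuclei, dtype=float)
    centrosomes = np.asarray(centrosomes, dtype=float)
    d_nn = float(np.linalg.norm(nuclei[0] - nuclei[1]))
    d_cc = float(np.linalg.norm(centrosomes[0] - centrosomes[1]))
    if d_nn == 0 or d_cc == 0:
        raise ValueError("coincident nuclei or centrosomes")
    return d_nn / d_cc


def analyze_pair(img: CalibratedImage, cfg: AssayConfig) -> TwoCellRecord:
    """Measure d_nn/d_cc of one two-cell field.

    Requires exactly two nuclei after size filtering and 2–4 centrosome
    puncta; puncta are assigned to the nearest nucleus (optimal assignment,
    at most two per cell) and pooled to one intensity-weighted centroid per
    cell.
    """
    img.require_roles(["nucleus", "centrosome"])
    px = img.pixel_size

    nuc_proj = img.max_project("nucleus").astype(float)
    nuc_mask = threshold_mask(nuc_proj, "otsu")
    labels, n = ndi.label(nuc_mask, structure=np.ones((3, 3), dtype=int))
    lo, hi = cfg.nucleus_area_range
    nuclei = []
    for lab in range(1, n + 1):
        m = labels == lab
        if lo <= m.sum() * px**2 <= hi:
            nuclei.append(np.array(_centroid_xy(m, px, weights=nuc_proj)))
    if len(nuclei) != 2:
        raise ValueError(f"expected exactly 2 nuclei, found {len(nuclei)}")

    puncta = _detect_puncta(img.max_project("centrosome"), px, max_puncta=4)
    if len(puncta) < 2:
        raise ValueError(f"expected 2-4 centrosome puncta, found {len(puncta)}")
    pos = np.array([(p[0], p[1]) for p in puncta])
    w = np.array([p[2] for p in puncta])

    # assign each punctum to a nucleus (<= 2 per cell) minimising total distance:
    # slots [n1, n1, n2, n2] vs puncta, optimal assignment
    slots = np.repeat(np.arange(2), 2)
    slot_pos = np.array([nuclei[i] for i in slots])
    cost = np.linalg.norm(pos[:, None, :] - slot_pos[None, :, :], axis=2)
    ri, ci = linear_sum_assignment(cost)
    cents, flag = [], ""
    for cell in range(2):
        sel = [r for r, c in zip(ri, ci) if slots[c] == cell]
        if not sel:
            raise ValueError(f"no centrosome matched to nucleus {cell + 1}")
        cents.append((pos[sel] * w[sel, None]).sum(axis=0) / w[sel].sum())

    d_nn = float(np.linalg.norm(nuclei[0] - nuclei[1]))
    d_cc = float(np.linalg.norm(cents[0] - cents[1]))
    if d_cc < MIN_DCC_UM:
        flag = f"d_cc below {MIN_DCC_UM} µm"
    return TwoCellRecord(
        nucleus_1=tuple(nuclei[0]),
        nucleus_2=tuple(nuclei[1]),
        centrosome_1=tuple(cents[0]),
        centrosome_2=tuple(cents[1]),
        d_nn=d_nn,
        d_cc=d_cc,
        ratio=d_nn / d_cc if d_cc > 0 else float("inf"),
        pattern_area=cfg.pattern_area,
        flag=flag,
    )


def compare_ratio_groups(groups: dict[str, np.ndarray]) -> dict:
    """Group medians and Mann-Whitney rank-sum comparison of ratio samples.

    Returns medians, the percent difference of medians (second vs first
    group), and the two-sided Mann-Whitney U p-value.
    """
    if len(groups) < 2:
        raise ValueError("need two groups")
    names = list(groups)
    for name in names:
        if len(groups[name]) < 10:
            raise ValueError(f"group {name!r} needs n >= 10")
    medians = {k: float(np.median(v)) for k, v in groups.items()}
    a, b = (np.asarray(groups[n], dtype=float) for n in names[:2])
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    ref = medians[names[0]]
    return {
        "medians": medians,
        "pct_difference_of_medians": (medians[names[1]] - ref) / ref * 100.0,
        "U": float(stat),
        "pvalue": float(p),
        "method": "Mann-Whitney rank-sum",
    }


def records_table(records: list[TwoCellRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in records])
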