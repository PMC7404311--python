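"""Rule-based five-group polarity classification of spheroid z-stacks.

The five phenotypes (classically scored by eye on 4-colour stacks) are encoded
as explicit rules on three measured properties:

1. correctly polarized, complete sphere: apical marker faces a single lumen,
   the cell shell covers (almost) the full solid angle;
2. correctly polarized, partial sphere: as 1 with an incomplete shell;
3. inversely polarized, complete: apical marker on the matrix-facing outer
   surface, centre filled with cells;
4. inversely polarized, partial;
5. unpolarized aggregate: mixed or absent marker orientation, no lumen or
   multiple lumina, or no coherent shell.

The stack is analysed on a ~0.5 µm isotropic grid (voxel distances in
physical units, so anisotropic acquisitions are handled): the spheroid body is
segmented, interior cavities are found by ray-casting from the body centroid,
apical-marker enrichment is compared between cavity-facing and matrix-facing
boundary shells, and shell completeness is the fraction of solid angle covered
by cell material.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.spatial import cKDTree
from skimage import feature, measure

from micromorph.io_core import AssayConfig, CalibratedImage
from micromorph.synthetic_data import fibonacci_sphere

#: shell covering at least this solid-angle fraction counts as "complete"
COMPLETE_COVERAGE = 0.90
#: below this the object is no coherent shell at all (contributes to group 5)
MIN_COVERAGE = 0.40
#: apical enrichment factor required to call an orientation
ORIENTATION_RATIO = 1.5
#: smallest cavity volume accepted as a lumen (µm³)
MIN_LUMEN_VOLUME = 30.0
#: working grid spacing (µm)
GRID_UM = 0.5


@dataclass
class SpheroidCall:
    """Classification of one spheroid with its evidence."""

    group: int
    n_cells: int
    lumen_found: bool
    n_lumina: int
    apical_orientation: str  # {inner, outer, mixed, none}
    shell_complete: bool
    shell_coverage: float
    evidence: dict = field(default_factory=dict)
    flags: str = ""

    def to_row(self) -> dict:
        return {
            "group": self.group,
            "n_cells": self.n_cells,
            "n_lumina": self.n_lumina,
            "apical_orientation": self.apical_orientation,
            "shell_coverage": self.shell_coverage,
            "flags": self.flags,
        }


def _sphere_center(body: np.ndarray) -> np.ndarray:
    """Centre (voxel coords) of the algebraic least-squares sphere through the
    exterior-facing surface voxels; falls back to the centroid when the fit
    lands outside the body's bounding box."""
    centroid = np.array(ndi.center_of_mass(body))
    surface = body & ~ndi.binary_erosion(body)
    pts = np.argwhere(surface).astype(float)
    if len(pts) < 30:
        return centroid
    # |x|^2 = 2 c·x + (R^2 - |c|^2): linear least squares in (c, k)
    A = np.hstack([2 * pts, np.ones((len(pts), 1))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    lo, hi = np.argwhere(body).min(axis=0), np.argwhere(body).max(axis=0)
    if np.any(center < lo - 2) or np.any(center > hi + 2):
        return centroid
    return center


def _resample_iso(channel: np.ndarray, pixel_size: float, z_step: float) -> np.ndarray:
    """Resample (z, y, x) data to an approximately isotropic GRID_UM grid."""
    fz = GRID_UM / z_step
    fy = fx = GRID_UM / pixel_size
    bz, by, bx = max(1, round(fz)), max(1, round(fy)), max(1, round(fx))
    out = measure.block_reduce(channel.astype(float), (bz, by, bx), np.mean)
    return out


def classify_spheroid(stack: CalibratedImage, cfg: AssayConfig | None = None) -> SpheroidCall:
    """Classify a 4-channel spheroid z-stack into polarity groups 1-5."""
    stack.require_roles(["nucleus", "apical", "basolateral", "actin"])
    if stack.nz < 5:
        raise ValueError("need a z-stack of at least 5 planes")
    px, zs = stack.pixel_size, stack.z_step

    chans = {
        role: _resample_iso(stack.channel(role), px, zs)
        for role in ("nucleus", "apical", "basolateral", "actin")
    }
    # Remove each channel's smooth background (lamp tilt + pedestal).  The
    # per-column z-minimum is background everywhere (every column contains
    # background planes above/below the spheroid), so a plane fitted to it
    # captures the lateral unevenness without touching the structure.
    sm = {}
    for k, v in chans.items():
        zmin = v.min(axis=0)
        yy, xx = np.mgrid[: zmin.shape[0], : zmin.shape[1]]
        A = np.stack([np.ones(zmin.size), yy.ravel(), xx.ravel()], axis=1)
        coef, *_ = np.linalg.lstsq(A, zmin.ravel(), rcond=None)
        plane = (A @ coef).reshape(zmin.shape)
        sm[k] = ndi.gaussian_filter(v - plane[None], 1.0)

    total = sum(sm.values())
    med = float(np.median(total))
    mad = float(np.median(np.abs(total - med))) * 1.4826
    # With the background plane removed, anything clearly above the noise is
    # cell material.  (A histogram split such as Otsu is wrong here: it can
    # land between dim cytoplasm and bright marker bands and cut the shell in
    # two, leaving a phantom cavity between them.)
    thr = med + 4 * mad
    body = total > thr
    body = ndi.binary_opening(body, np.ones((2, 2, 2)))
    labels, n = ndi.label(body)
    if n == 0:
        raise ValueError("no spheroid body found")
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    body = labels == (int(np.argmax(sizes)) + 1)

    flags = ""
    edge = np.zeros_like(body)
    edge[:, 0, :] = edge[:, -1, :] = edge[:, :, 0] = edge[:, :, -1] = True
    if (body & edge).any():
        flags = "truncated: body touches image border"

    # --- ray-cast shell geometry ------------------------------------------
    # Viewpoint: centre of the sphere fitted to the exterior-facing surface.
    # The raw body centroid shifts away from any missing cap, which would make
    # the opening look smaller than it is from inside.
    centroid = _sphere_center(body)
    dirs = fibonacci_sphere(500)
    tree = cKDTree(dirs)
    vox = np.argwhere(body)
    rel = (vox - centroid) * GRID_UM
    r = np.linalg.norm(rel, axis=1)
    nz = r > 1e-9
    _, bins = tree.query(rel[nz] / r[nz, None])
    r_out = np.zeros(len(dirs))
    np.maximum.at(r_out, bins, r[nz])
    covered = r_out > 0
    med_r = np.median(r_out[covered]) if covered.any() else 0.0
    coverage = float((r_out >= 0.85 * med_r).mean()) if med_r > 0 else 0.0

    # --- interior cavities (lumen candidates) -------------------------------
    allvox = np.argwhere(~body)
    rel_bg = (allvox - centroid) * GRID_UM
    r_bg = np.linalg.norm(rel_bg, axis=1)
    nz_bg = r_bg > 1e-9
    interior = np.zeros(len(allvox), dtype=bool)
    _, bins_bg = tree.query(rel_bg[nz_bg] / r_bg[nz_bg, None])
    lim = r_out[bins_bg] - 1.0
    interior[nz_bg] = (r_out[bins_bg] > 0) & (r_bg[nz_bg] < lim)
    interior[~nz_bg] = True  # the centroid voxel itself, if background
    interior_mask = np.zeros_like(body)
    interior_mask[tuple(allvox[interior].T)] = True

    # label on a lightly closed mask so a one-voxel noise tendril crossing a
    # cavity does not split it in two; volumes are measured on the raw mask
    closed_interior = ndi.binary_closing(interior_mask, structure=np.ones((3, 3, 3)))
    cav_labels, n_cav = ndi.label(closed_interior, structure=np.ones((3, 3, 3)))
    cav_labels[~interior_mask] = 0
    voxel_vol = GRID_UM**3
    lumina = [
        lab
        for lab in range(1, n_cav + 1)
        if (cav_labels == lab).sum() * voxel_vol >= MIN_LUMEN_VOLUME
    ]
    n_lumina = len(lumina)
    lumen_mask = np.isin(cav_labels, lumina)

    # --- apical orientation -------------------------------------------------
    exterior = ~body & ~interior_mask
    dist_ext = ndi.distance_transform_edt(~exterior) * GRID_UM
    outer_shell = body & (dist_ext <= 1.2)
    if n_lumina >= 1:
        dist_lum = ndi.distance_transform_edt(~lumen_mask) * GRID_UM
        inner_shell = body & (dist_lum <= 1.2)
    else:
        inner_shell = body & (dist_ext > 2.5)  # the body core stands in

    # Orientation needs *complementary* marker placement, as a rater would
    # demand: apical enriched on one boundary and basolateral on the other.
    ap, ba = sm["apical"], sm["basolateral"]
    noise_floor = 1.5 * float(np.std(ap[exterior])) if exterior.any() else 0.0
    mean_in = float(ap[inner_shell].mean()) if inner_shell.any() else 0.0
    mean_out = float(ap[outer_shell].mean()) if outer_shell.any() else 0.0
    ba_in = float(ba[inner_shell].mean()) if inner_shell.any() else 0.0
    ba_out = float(ba[outer_shell].mean()) if outer_shell.any() else 0.0
    eps = noise_floor + 1e-9
    ap_score = (mean_in - mean_out) / (abs(mean_in) + abs(mean_out) + eps)
    ba_score = (ba_in - ba_out) / (abs(ba_in) + abs(ba_out) + eps)
    t = 1 - 2 / (1 + ORIENTATION_RATIO)  # enrichment ratio mapped to a score
    if max(mean_in, mean_out) <= noise_floor:
        orientation = "none"
    elif ap_score > t and ba_score < -t and n_lumina >= 1:
        orientation = "inner"
    elif ap_score < -t and ba_score > t:
        orientation = "outer"
    else:
        orientation = "mixed"

    # --- nucleus count ------------------------------------------------------
    # Count nuclei on the distance transform of the thresholded nucleus mask:
    # its maxima are set by blob geometry, so nearly-touching nuclei that merge
    # into one intensity blob still contribute two centres.
    nuc = sm["nucleus"]
    nuc_thr = 0.45 * np.percentile(nuc, 99.9)
    nuc_mask = nuc > nuc_thr
    edt = ndi.distance_transform_edt(nuc_mask)
    rad = 2
    zz, yy, xx = np.mgrid[-rad : rad + 1, -rad : rad + 1, -rad : rad + 1]
    footprint = zz**2 + yy**2 + xx**2 <= rad**2
    peaks = feature.peak_local_max(edt, footprint=footprint, threshold_abs=1.2, labels=nuc_mask)
    centres: list[np.ndarray] = []
    for p in peaks:  # de-duplicate plateau maxima of the same nucleus
        if all(np.linalg.norm(p - q) > 3.0 for q in centres):
            centres.append(p)
    n_cells = int(len(centres))

    # --- rules --------------------------------------------------------------
    shell_complete = coverage >= COMPLETE_COVERAGE
    if orientation == "inner" and n_lumina == 1 and coverage >= MIN_COVERAGE:
        group = 1 if shell_complete else 2
    elif orientation == "outer" and n_lumina <= 1 and coverage >= MIN_COVERAGE:
        # inverted cysts have a matrix-filled centre; several cavities mean
        # an aggregate whatever the surface staining looks like
        group = 3 if shell_complete else 4
    else:
        group = 5

    return SpheroidCall(
        group=group,
        n_cells=n_cells,
        lumen_found=n_lumina >= 1,
        n_lumina=n_lumina,
        apical_orientation=orientation,
        shell_complete=shell_complete,
        shell_coverage=coverage,
        evidence={
            "apical_mean_inner": mean_in,
            "apical_mean_outer": mean_out,
            "noise_floor": noise_floor,
            "median_radius_um": float(med_r),
        },
        flags=flags,
    )


def calls_table(calls: list[SpheroidCall], condition: str | None = None) -> pd.DataFrame:
    df = pd.DataFrame([c.to_row() for c in calls])
    if condition is not None:
        df.insert(0, "condition", condition)
    return df


def tabulate_groups(calls: pd.DataFrame) -> dict:
    """Per-condition group distribution (%) and between-condition comparison.

    ``calls`` needs columns ``condition`` and ``group`` and, optionally,
    ``experiment``.  With per-experiment replication the comparison is a
    per-group one-way ANOVA on per-experiment percentages (mirroring the
    ANOVA-on-percentages convention for such assays); without it, a chi-square
    test on the pooled contingency table.
    """
    if calls.empty:
        raise ValueError("no calls")
    if calls.groupby("condition").size().min() == 0:
        raise ValueError("empty condition")
    counts = calls.pivot_table(index="condition", columns="group", aggfunc="size", fill_value=0)
    counts = counts.reindex(columns=range(1, 6), fill_value=0)
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0

    tests: dict[int, dict] = {}
    if "experiment" in calls.columns and calls["experiment"].nunique() > 1:
        from scipy.stats import f_oneway

        per_exp = (
            calls.pivot_table(
                index=["condition", "experiment"], columns="group", aggfunc="size", fill_value=0
            )
            .reindex(columns=range(1, 6), fill_value=0)
        )
        per_exp_pct = per_exp.div(per_exp.sum(axis=1), axis=0) * 100.0
        for g in range(1, 6):
            samples = [
                per_exp_pct.loc[cond][g].to_numpy()
                for cond in pct.index
            ]
            if len(samples) >= 2 and all(len(s) >= 2 for s in samples):
                F, p = f_oneway(*samples)
                tests[g] = {"F": float(F), "pvalue": float(p)}
    elif len(pct.index) >= 2:
        from scipy.stats import chi2_contingency

        observed = counts.loc[:, counts.sum(axis=0) > 0].to_numpy() + 0.0
        chi2, p, dof, _ = chi2_contingency(observed)
        tests["overall"] = {"chi2": float(chi2), "pvalue": float(p), "dof": int(dof)}

    return {"counts": counts, "percent": pct, "tests": tests}
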