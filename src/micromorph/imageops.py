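"""Segmentation primitives: background subtraction, thresholding, cell masking, labeling.

Everything here works on single-channel 2D planes plus a pixel calibration, and
returns measurements in physical units (µm, µm²).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage import filters, measure, transform

logger = logging.getLogger(__name__)


@dataclass
class LabeledRegions:
    """Connected components of a binary mask with per-region measurements.

    ``table`` columns: label, area_um2, centroid_y_um, centroid_x_um,
    major_axis_um, minor_axis_um, mean_intensity (NaN when no intensity image
    was supplied).
    """

    label_image: np.ndarray
    table: pd.DataFrame
    pixel_size: float

    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def total_area_um2(self) -> float:
        return float(self.table["area_um2"].sum())


def rolling_ball_subtract(
    image: np.ndarray,
    radius_um: float,
    pixel_size: float,
    *,
    fast: bool = True,
) -> np.ndarray:
    """Subtract a smooth background estimated by the rolling-ball algorithm.

    The background is the surface traced by a ball of the given radius rolled
    under the intensity landscape (a grayscale opening with a ball structuring
    element); structures smaller than the ball survive subtraction, smooth
    background does not.  The result is clipped at zero.

    For radii much larger than a pixel the exact computation is redundant —
    the background is smooth by construction — so by default the image is
    down-sampled such that the ball radius is ~16 px, the background estimated
    there, and re-interpolated to full resolution.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2D plane")
    radius_px = radius_um / pixel_size
    if radius_px < 1:
        raise ValueError(
            f"rolling-ball radius {radius_um} µm is below 1 px at {pixel_size} µm/px"
        )
    shrink = max(1, int(radius_px / 12)) if fast else 1
    if shrink > 1:
        small = transform.downscale_local_mean(image, (shrink, shrink))
        bg_small = _ball_opening(small, radius_px / shrink)
        bg = transform.resize(bg_small, image.shape, order=1, mode="edge", anti_aliasing=False)
        # re-interpolated background may slightly overshoot the data; a rolled
        # ball never does, so cap it at the local minimum-filtered image
        bg = np.minimum(bg, ndi.minimum_filter(image, size=max(3, shrink)))
    else:
        bg = _ball_opening(image, radius_px)
    return np.clip(image - bg, 0, None)


def _ball_opening(image: np.ndarray, radius_px: float) -> np.ndarray:
    """Grayscale opening with a spherical (ball) structuring element.

    This is the rolling-ball background: the surface traced by the top of a
    ball of the given radius rolled under the intensity landscape.
    """
    r = int(np.ceil(radius_px))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    inside = yy**2 + xx**2 <= radius_px**2
    heights = np.sqrt(np.clip(radius_px**2 - yy**2 - xx**2, 0, None))
    return ndi.grey_opening(image, footprint=inside, structure=heights, mode="nearest")


def otsu_threshold(values: np.ndarray) -> float:
    """Exact Otsu threshold: maximises between-class variance over all splits.

    Works on the exact sample values (prefix sums over the sorted unique
    values) rather than a binned histogram, so the returned threshold is the
    true maximiser for discrete data as well; it is placed midway between the
    two classes' boundary values.
    """
    uniq, counts = np.unique(np.asarray(values, dtype=float).ravel(), return_counts=True)
    if len(uniq) < 2:
        raise ValueError("constant input: Otsu threshold undefined")
    w = np.cumsum(counts)[:-1]  # lower-class counts for split after uniq[i]
    total = counts.sum()
    s = np.cumsum(counts * uniq)[:-1]
    mu0 = s / w
    mu1 = (s[-1] + counts[-1] * uniq[-1] - s) / (total - w)
    var_between = (w / total) * (1 - w / total) * (mu0 - mu1) ** 2
    i = int(np.argmax(var_between))
    return float((uniq[i] + uniq[i + 1]) / 2)


def threshold_mask(
    image: np.ndarray,
    method: str | float = "otsu",
    roi: np.ndarray | None = None,
) -> np.ndarray:
    """Binary mask by intensity thresholding (Otsu or a fixed value).

    When ``roi`` is given, the threshold is computed from ROI pixels only and
    the mask is restricted to the ROI.
    """
    image = np.asarray(image, dtype=float)
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != image.shape:
            raise ValueError("roi shape must match image")
        if not roi.any():
            raise ValueError("empty ROI")
        values = image[roi]
    else:
        values = image.ravel()

    if isinstance(method, (int, float)) and not isinstance(method, bool):
        thresh = float(method)
    elif method == "otsu":
        if values.min() == values.max():
            raise ValueError(
                "constant image: Otsu threshold undefined; use a fixed threshold value"
            )
        thresh = otsu_threshold(values)
    else:
        raise ValueError(f"unknown threshold method {method!r}")

    mask = image > thresh
    if roi is not None:
        mask &= roi
    return mask


def _dilate_disk(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """Binary dilation with a euclidean disk via the distance transform."""
    return ndi.distance_transform_edt(~mask) <= radius_px


def _erode_disk(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """Binary erosion with a euclidean disk via the distance transform."""
    return ndi.distance_transform_edt(mask) > radius_px


def edge_cell_mask(
    image: np.ndarray,
    pixel_size: float,
    smoothing_um: float = 1.0,
    min_cell_area_um2: float = 50.0,
) -> np.ndarray | None:
    """Whole-cell mask via edge detection on a cytoplasmic stain.

    Gaussian-derivative gradient magnitude → Otsu threshold on the gradient →
    morphological closing → hole filling give the edge-bounded region; its
    boundary is then refined to the intensity half-way point between the
    median interior and median exterior level (the blurred-step midpoint, i.e.
    the physical cell outline; the raw gradient band is ~±σ wide and would
    bias the area high).  Exactly one cell is assumed per field; if several
    candidate regions remain, the largest is kept (ties broken by the smallest
    label) and the event is logged.

    Returns ``None`` ("no cell") when no region of at least
    ``min_cell_area_um2`` is found.
    """
    image = np.asarray(image, dtype=float)
    sigma = max(smoothing_um / pixel_size, 1.0)
    sm = ndi.gaussian_filter(image, sigma)
    grad = filters.sobel(sm)
    if grad.max() == grad.min():
        return None
    edges = grad > filters.threshold_otsu(grad)
    closed = _erode_disk(_dilate_disk(edges, max(2, int(sigma))), max(2, int(sigma)))
    band = ndi.binary_fill_holes(closed)
    if not band.any() or band.all():
        return None
    core = _erode_disk(band, int(2 * sigma))
    outside = _dilate_disk(band, int(2 * sigma)) & ~band
    if core.any() and outside.any():
        med_in, med_out = np.median(sm[core]), np.median(sm[outside])
        noise = 1.4826 * np.median(np.abs(sm[outside] - med_out)) + 1e-12
        if med_in - med_out < 4 * noise:  # no real interior/exterior contrast
            logger.info("edge_cell_mask: interior contrast below noise, no cell")
            return None
        half_max = 0.5 * (med_in + med_out)
        filled = ndi.binary_fill_holes(band & (sm > half_max))
    else:
        filled = band
    labels, n = ndi.label(filled, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        logger.info("edge_cell_mask: no region found")
        return None
    sizes = ndi.sum_labels(np.ones_like(labels, dtype=float), labels, index=range(1, n + 1))
    keep = int(np.argmax(sizes)) + 1  # argmax returns first max → smallest label wins ties
    if n > 1:
        logger.info("edge_cell_mask: %d candidate regions, keeping largest (label %d)", n, keep)
    if sizes[keep - 1] * pixel_size**2 < min_cell_area_um2:
        logger.info("edge_cell_mask: no region >= %.1f µm² found", min_cell_area_um2)
        return None
    return labels == keep


def label_and_measure(
    mask: np.ndarray,
    pixel_size: float,
    min_area_um2: float = 0.0,
    intensity_image: np.ndarray | None = None,
) -> LabeledRegions:
    """8-connected components of a binary mask with calibrated measurements.

    Regions smaller than ``min_area_um2`` are discarded; remaining labels are
    renumbered contiguously from 1.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=2)
    props = ["label", "area", "centroid", "axis_major_length", "axis_minor_length"]
    if intensity_image is not None:
        props.append("intensity_mean")
    if labels.max() == 0:
        table = pd.DataFrame(
            columns=[
                "label",
                "area_um2",
                "centroid_y_um",
                "centroid_x_um",
                "major_axis_um",
                "minor_axis_um",
                "mean_intensity",
            ]
        )
        return LabeledRegions(label_image=labels, table=table, pixel_size=pixel_size)

    t = pd.DataFrame(
        measure.regionprops_table(labels, intensity_image=intensity_image, properties=props)
    )
    t["area_um2"] = t["area"] * pixel_size**2
    t["centroid_y_um"] = t["centroid-0"] * pixel_size
    t["centroid_x_um"] = t["centroid-1"] * pixel_size
    t["major_axis_um"] = t["axis_major_length"] * pixel_size
    t["minor_axis_um"] = t["axis_minor_length"] * pixel_size
    t["mean_intensity"] = t["intensity_mean"] if intensity_image is not None else np.nan

    keep = t["area_um2"] >= min_area_um2
    t = t[keep].reset_index(drop=True)

    # renumber contiguously via a lookup table, preserving label order
    lut = np.zeros(labels.max() + 1, dtype=labels.dtype)
    lut[t["label"].to_numpy()] = np.arange(1, len(t) + 1)
    out = lut[labels]
    t["label"] = np.arange(1, len(t) + 1)

    cols = [
        "label",
        "area_um2",
        "centroid_y_um",
        "centroid_x_um",
        "major_axis_um",
        "minor_axis_um",
        "mean_intensity",
    ]
    return LabeledRegions(label_image=out, table=t[cols], pixel_size=pixel_size)
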