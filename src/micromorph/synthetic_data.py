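"""Synthetic fluorescence microscopy with ground truth.

Generates every input the analysis stages consume, emulating the assays the
pipeline is built for:

* single cells on disc (700/1600 µm²) or crossbow (1100 µm²) micropatterns,
  with vinculin adhesion puncta, nucleus and centrosome channels,
* two-cell stages with a planted nuclear/centrosomal distance ratio,
* 16–20-cell spheroid z-stacks realising the five polarity phenotypes,
* qPCR CT tables and immunoblot band intensities with planted effects.

Images carry Poisson shot noise, Gaussian read noise and a smooth uneven
background.  Every generator returns a :class:`SceneTruth` holding the planted
geometry, so recovery can be scored exactly; the same seed reproduces pixels
bit-exactly.

Coordinates in truth records are (x, y) in µm, origin at the field centre,
+y pointing up (mathematical convention); the rasteriser converts to array
rows/columns internally.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from micromorph.io_core import CalibratedImage

# --- default acquisition geometry -----------------------------------------
PIXEL_SIZE = 0.1  # µm/px, 63x/1.4NA-class sampling
FIELD_PX = 512  # single-cell and two-cell fields
SPHEROID_FIELD_PX = 256
SPHEROID_PLANES = 40
Z_STEP = 0.5  # µm

# --- default photon budget -------------------------------------------------
BACKGROUND = 100.0  # mean background photon count
BACKGROUND_GRADIENT = 20.0  # peak-to-peak smooth background unevenness
READ_NOISE_SD = 3.0
CYTO_VINCULIN = 30.0  # diffuse cytoplasmic vinculin above background
CYTO_ACTIN = 40.0
NUCLEUS_AMP = 80.0
PATTERN_AMP = 80.0
PSF_SIGMA_UM = 0.08  # Gaussian stand-in for the microscope PSF

#: channel layout of all 2D synthetic fields
CELL_CHANNELS = {"pattern": 0, "actin": 1, "vinculin": 2, "nucleus": 3, "centrosome": 4}
#: channel layout of spheroid stacks
SPHEROID_CHANNELS = {"nucleus": 0, "actin": 1, "apical": 2, "basolateral": 3}

PATTERNS = {
    "disc700": ("disc", 700.0),
    "disc1600": ("disc", 1600.0),
    "crossbow1100": ("crossbow", 1100.0),
}


@dataclass
class SceneTruth:
    """Ground truth serialized alongside every generated image."""

    kind: str
    pixel_size: float
    seed: int
    z_step: float | None = None
    params: dict = field(default_factory=dict)
    pattern: dict | None = None
    cell: dict | None = None
    sites: list | None = None
    nucleus: dict | None = None
    centrosomes: list | None = None
    angle_deg: float | None = None
    nuclei: list | None = None
    ratio: float | None = None
    group: int | None = None
    n_cells: int | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "SceneTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _grids_um(shape: tuple[int, int], pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) coordinate grids in µm, origin at field centre, +y up."""
    ny, nx = shape
    x = (np.arange(nx) - (nx - 1) / 2) * pixel_size
    y = ((ny - 1) / 2 - np.arange(ny)) * pixel_size
    return np.meshgrid(x, y)


def ellipse_mask(
    shape_px: tuple[int, int],
    center_um: tuple[float, float],
    semi_axes_um: tuple[float, float],
    angle_deg: float = 0.0,
    pixel_size: float = PIXEL_SIZE,
) -> np.ndarray:
    """Rasterize a filled ellipse given in physical coordinates.

    ``semi_axes_um`` are the (major, minor) semi-axes; ``angle_deg`` is the
    major-axis direction measured from +x.  A circle of radius r is
    ``semi_axes_um=(r, r)``.
    """
    ny, nx = shape_px
    a, b = semi_axes_um
    th = np.deg2rad(angle_deg)
    # rasterize only a local bounding window (big speed-up for small puncta)
    cx, cy = center_um
    col_c = (nx - 1) / 2 + cx / pixel_size
    row_c = (ny - 1) / 2 - cy / pixel_size
    r_px = max(a, b) / pixel_size + 2
    r0, r1 = max(0, int(row_c - r_px)), min(ny, int(np.ceil(row_c + r_px)) + 1)
    c0, c1 = max(0, int(col_c - r_px)), min(nx, int(np.ceil(col_c + r_px)) + 1)
    out = np.zeros(shape_px, dtype=bool)
    if r0 >= r1 or c0 >= c1:
        return out
    cols = np.arange(c0, c1)
    rows = np.arange(r0, r1)
    X = (cols - (nx - 1) / 2)[None, :] * pixel_size - cx
    Y = ((ny - 1) / 2 - rows)[:, None] * pixel_size - cy
    u = X * np.cos(th) + Y * np.sin(th)
    v = -X * np.sin(th) + Y * np.cos(th)
    out[r0:r1, c0:c1] = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return out


def crossbow_mask(
    shape_px: tuple[int, int],
    envelope_area_um2: float = 1100.0,
    orientation_deg: float = 0.0,
    pixel_size: float = PIXEL_SIZE,
    arc_thickness_um: float = 3.0,
    stem_width_um: float = 3.0,
) -> np.ndarray:
    """Printed crossbow micropattern: an arc ("bow", the cell front) plus a stem.

    ``envelope_area_um2`` is the area of the circular envelope the cell can
    spread over (the conventional size designation of such patterns).  In the
    canonical orientation (``orientation_deg=0``) the arc opens towards +y.
    """
    r_env = np.sqrt(envelope_area_um2 / np.pi)
    X, Y = _grids_um(shape_px, pixel_size)
    th = np.deg2rad(orientation_deg)
    # pattern-frame coordinates (rotate by -orientation)
    xp = X * np.cos(th) + Y * np.sin(th)
    yp = -X * np.sin(th) + Y * np.cos(th)
    r = np.hypot(xp, yp)
    phi = np.degrees(np.arctan2(yp, xp))
    arc = (r <= r_env) & (r >= r_env - arc_thickness_um) & (phi >= 15) & (phi <= 165)
    stem = (np.abs(xp) <= stem_width_um / 2) & (yp <= 0) & (yp >= -r_env)
    return arc | stem


def pattern_mask(
    pattern: str,
    shape_px: tuple[int, int],
    orientation_deg: float = 0.0,
    pixel_size: float = PIXEL_SIZE,
) -> np.ndarray:
    """Rasterize a named micropattern (printed ECM shape)."""
    shape, area = PATTERNS[pattern]
    if shape == "disc":
        r = np.sqrt(area / np.pi)
        return ellipse_mask(shape_px, (0.0, 0.0), (r, r), 0.0, pixel_size)
    return crossbow_mask(shape_px, area, orientation_deg, pixel_size)


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors on the sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + np.sqrt(5)) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


# ---------------------------------------------------------------------------
# noise model
# ---------------------------------------------------------------------------

def _background_field(
    shape: tuple[int, int],
    rng: np.random.Generator,
    level: float = BACKGROUND,
    gradient: float = BACKGROUND_GRADIENT,
) -> np.ndarray:
    """Smooth uneven background: mean level plus a random linear tilt."""
    X, Y = _grids_um(shape, 1.0)  # unit spacing; only relative extent matters
    direction = rng.uniform(0, 2 * np.pi)
    ramp = X * np.cos(direction) + Y * np.sin(direction)
    ramp = ramp / max(np.abs(ramp).max(), 1e-9)
    return level + gradient / 2 * ramp


def _apply_noise(expected: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Poisson shot noise + Gaussian read noise, clipped to uint16 range."""
    noisy = rng.poisson(np.clip(expected, 0, None)).astype(np.float64)
    noisy += rng.normal(0.0, READ_NOISE_SD, size=noisy.shape)
    return np.clip(np.round(noisy), 0, 65535).astype(np.uint16)


def site_amplitude(snr: float) -> float:
    """Peak signal above background for a punctum of the requested SNR.

    SNR is defined against the background noise floor
    sqrt(background + read_sd²).
    """
    return snr * np.sqrt(BACKGROUND + READ_NOISE_SD**2)


# ---------------------------------------------------------------------------
# single cells
# ---------------------------------------------------------------------------

_CELL_DEFAULTS = {  # per-pattern (cell_area µm², circularity)
    "disc700": (630.0, 0.92),
    "disc1600": (690.0, 0.65),
    "crossbow1100": (950.0, 0.90),
}


def _place_sites(
    rng: np.random.Generator,
    n_sites: int,
    site_area_range: tuple[float, float],
    cell_center: tuple[float, float],
    cell_semi: tuple[float, float],
    cell_angle_deg: float,
    site_areas: Sequence[float] | None = None,
) -> list[dict]:
    """Plant non-overlapping adhesion-site ellipses inside the cell."""
    lo, hi = site_area_range
    areas = np.asarray(site_areas, float) if site_areas is not None else rng.uniform(lo, hi, size=n_sites)
    th = np.deg2rad(cell_angle_deg)
    placed: list[dict] = []
    for area in areas:
        r_eq = np.sqrt(area / np.pi)
        ok = False
        for _ in range(4000):
            # uniform point in the shrunk cell ellipse
            u, v = rng.uniform(-1, 1, 2)
            if u * u + v * v > 1:
                continue
            margin = r_eq * 1.4 + 0.3
            ax = max(cell_semi[0] - margin, 0.5)
            ay = max(cell_semi[1] - margin, 0.5)
            px = u * ax
            py = v * ay
            x = cell_center[0] + px * np.cos(th) - py * np.sin(th)
            y = cell_center[1] + px * np.sin(th) + py * np.cos(th)
            min_sep_ok = all(
                np.hypot(x - s["x_um"], y - s["y_um"])
                > r_eq * 1.4 + np.sqrt(s["area_um2"] / np.pi) * 1.4 + 0.3
                for s in placed
            )
            if min_sep_ok:
                ok = True
                break
        if not ok:
            raise ValueError(
                f"cannot place {n_sites} non-overlapping sites of area up to {hi} µm² "
                "inside the cell: geometry infeasible"
            )
        q = rng.uniform(0.6, 1.0)  # site elongation
        placed.append(
            {
                "x_um": float(x),
                "y_um": float(y),
                "area_um2": float(area),
                "axis_ratio": float(q),
                "angle_deg": float(rng.uniform(0, 180)),
            }
        )
    return placed


def make_single_cell(
    pattern: str = "disc700",
    cell_area: float | None = None,
    circ: float | None = None,
    n_sites: int = 30,
    site_area_range: tuple[float, float] = (0.1, 2.0),
    snr: float = 10.0,
    seed: int = 0,
    centrosome_offset_um: float = 4.0,
    centrosome_angle_deg: float = 90.0,
    orientation_deg: float = 0.0,
    pixel_size: float = PIXEL_SIZE,
    field_px: int = FIELD_PX,
    site_areas: Sequence[float] | None = None,
) -> tuple[CalibratedImage, SceneTruth]:
    """Render a single micropatterned cell with adhesion sites and polarity markers.

    The centrosome is planted at ``centrosome_offset_um`` from the nucleus
    centroid at ``centrosome_angle_deg`` (pattern frame, front = +y = 90°).
    ``orientation_deg`` rotates the whole scene (pattern and cell) in the
    image.
    """
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; choose from {sorted(PATTERNS)}")
    default_area, default_circ = _CELL_DEFAULTS[pattern]
    cell_area = default_area if cell_area is None else cell_area
    circ = default_circ if circ is None else circ
    if not 0 < circ <= 1:
        raise ValueError("circ must be in (0, 1]")
    rng = np.random.default_rng(seed)
    shape = (field_px, field_px)

    a_major = np.sqrt(cell_area / (np.pi * circ))
    a_minor = circ * a_major
    if 2 * a_major > field_px * pixel_size - 4:
        raise ValueError("cell does not fit within the field")
    # cell major axis perpendicular to the pattern front (elongation along x
    # in the pattern frame), rotated with the scene
    cell_angle = orientation_deg
    cell = ellipse_mask(shape, (0, 0), (a_major, a_minor), cell_angle, pixel_size)

    pat = pattern_mask(pattern, shape, orientation_deg, pixel_size)

    if site_areas is not None:
        n_sites = len(site_areas)
    sites = _place_sites(
        rng, n_sites, site_area_range, (0.0, 0.0), (a_major, a_minor), cell_angle, site_areas
    )
    site_img = np.zeros(shape)
    for s in sites:
        a_site = np.sqrt(s["area_um2"] / (np.pi * s["axis_ratio"]))
        b_site = s["axis_ratio"] * a_site
        m = ellipse_mask(shape, (s["x_um"], s["y_um"]), (a_site, b_site), s["angle_deg"], pixel_size)
        s["area_um2"] = float(m.sum() * pixel_size**2)  # truth = rasterized area
        site_img[m] = 1.0

    # nucleus offset slightly to the rear (pattern frame), rotated with scene
    th = np.deg2rad(orientation_deg)
    nuc_off = (-2.0 * -np.sin(th), -2.0 * np.cos(th))  # (x, y) of (0, -2) rotated
    nuc_semi = (min(5.0, a_minor * 0.6), min(4.0, a_minor * 0.5))
    nucleus = ellipse_mask(shape, nuc_off, nuc_semi, cell_angle, pixel_size)

    # centrosome: planted offset in the pattern frame, then scene-rotated
    ca = np.deg2rad(centrosome_angle_deg)
    off_pat = np.array([centrosome_offset_um * np.cos(ca), centrosome_offset_um * np.sin(ca)])
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    off_img = rot @ off_pat
    cen_xy = (nuc_off[0] + off_img[0], nuc_off[1] + off_img[1])
    # two centriole puncta straddling the true centrosome position
    perp = rot @ np.array([-np.sin(ca), np.cos(ca)])
    puncta = [
        (cen_xy[0] + 0.2 * perp[0], cen_xy[1] + 0.2 * perp[1]),
        (cen_xy[0] - 0.2 * perp[0], cen_xy[1] - 0.2 * perp[1]),
    ]

    amp = site_amplitude(snr)
    sigma_px = PSF_SIGMA_UM / pixel_size
    X, Y = _grids_um(shape, pixel_size)
    cen_img = np.zeros(shape)
    for (pxu, pyu) in puncta:
        cen_img += np.exp(-((X - pxu) ** 2 + (Y - pyu) ** 2) / (2 * 0.15**2))

    chans = np.zeros((1, 5, *shape))
    blur = lambda im: ndi.gaussian_filter(im, sigma_px)  # noqa: E731
    chans[0, CELL_CHANNELS["pattern"]] = blur(pat * PATTERN_AMP)
    chans[0, CELL_CHANNELS["actin"]] = blur(cell * CYTO_ACTIN)
    chans[0, CELL_CHANNELS["vinculin"]] = blur(cell * CYTO_VINCULIN + site_img * amp)
    chans[0, CELL_CHANNELS["nucleus"]] = blur(nucleus * NUCLEUS_AMP)
    chans[0, CELL_CHANNELS["centrosome"]] = cen_img * amp * 3

    bg = _background_field(shape, rng)
    pixels = np.stack([_apply_noise(c + bg, rng) for c in chans[0]])[None]

    truth = SceneTruth(
        kind="single_cell",
        pixel_size=pixel_size,
        seed=seed,
        params={
            "pattern": pattern,
            "snr": snr,
            "n_sites": n_sites,
            "site_area_range": list(site_area_range),
            "orientation_deg": orientation_deg,
        },
        pattern={
            "shape": PATTERNS[pattern][0],
            "area_um2": PATTERNS[pattern][1],
            "center_xy_um": [0.0, 0.0],
            "orientation_deg": orientation_deg,
        },
        cell={
            "center_xy_um": [0.0, 0.0],
            "semi_axes_um": [a_major, a_minor],
            "angle_deg": cell_angle,
            "area_um2": float(cell.sum() * pixel_size**2),
            "circ": circ,
        },
        sites=sites,
        nucleus={"center_xy_um": list(nuc_off), "semi_axes_um": list(nuc_semi)},
        centrosomes=[{"center_xy_um": [float(cen_xy[0]), float(cen_xy[1])]}],
        angle_deg=float(centrosome_angle_deg),
    )
    img = CalibratedImage(pixels=pixels, pixel_size=pixel_size, channels=dict(CELL_CHANNELS))
    return img, truth


# ---------------------------------------------------------------------------
# two-cell stages
# ---------------------------------------------------------------------------

def make_two_cell(
    planted_ratio: float = 2.0,
    pattern: str = "disc700",
    snr: float = 10.0,
    seed: int = 0,
    d_nn_um: float = 10.0,
    axis_angle_deg: float | None = None,
    pixel_size: float = PIXEL_SIZE,
    field_px: int = FIELD_PX,
) -> tuple[CalibratedImage, SceneTruth]:
    """Render a two-cell stage with an exactly planted d_nn/d_cc ratio.

    Nuclei sit at ±d_nn/2 and per-cell centrosomes at ±d_cc/2 along a common
    axis through the pattern centre, with d_cc = d_nn / planted_ratio.
    """
    if planted_ratio <= 0:
        raise ValueError("planted_ratio must be > 0")
    rng = np.random.default_rng(seed)
    shape = (field_px, field_px)
    d_cc = d_nn_um / planted_ratio
    r_env = np.sqrt(PATTERNS[pattern][1] / np.pi)
    if d_cc / 2 > r_env - 2 or d_nn_um / 2 > r_env - 4:
        raise ValueError("planted geometry does not fit on the pattern")
    ang = rng.uniform(0, 360) if axis_angle_deg is None else axis_angle_deg
    th = np.deg2rad(ang)
    u = np.array([np.cos(th), np.sin(th)])

    nuc_centers = [tuple(+d_nn_um / 2 * u), tuple(-d_nn_um / 2 * u)]
    cen_centers = [tuple(+d_cc / 2 * u), tuple(-d_cc / 2 * u)]

    pat = pattern_mask(pattern, shape, 0.0, pixel_size)
    body = ellipse_mask(shape, (0, 0), (r_env, r_env), 0, pixel_size)
    nuc_img = np.zeros(shape, dtype=bool)
    for c in nuc_centers:
        nuc_img |= ellipse_mask(shape, c, (4.0, 3.0), ang, pixel_size)

    amp = site_amplitude(snr)
    X, Y = _grids_um(shape, pixel_size)
    perp = np.array([-np.sin(th), np.cos(th)])
    cen_img = np.zeros(shape)
    for c in cen_centers:
        for sgn in (+1, -1):  # two centrioles per centrosome
            px, py = c[0] + sgn * 0.2 * perp[0], c[1] + sgn * 0.2 * perp[1]
            cen_img += np.exp(-((X - px) ** 2 + (Y - py) ** 2) / (2 * 0.15**2))

    sigma_px = PSF_SIGMA_UM / pixel_size
    blur = lambda im: ndi.gaussian_filter(im, sigma_px)  # noqa: E731
    chans = np.zeros((1, 5, *shape))
    chans[0, CELL_CHANNELS["pattern"]] = blur(pat * PATTERN_AMP)
    chans[0, CELL_CHANNELS["actin"]] = blur(body * CYTO_ACTIN)
    chans[0, CELL_CHANNELS["vinculin"]] = blur(body * CYTO_VINCULIN)
    chans[0, CELL_CHANNELS["nucleus"]] = blur(nuc_img * NUCLEUS_AMP)
    chans[0, CELL_CHANNELS["centrosome"]] = cen_img * amp * 3

    bg = _background_field(shape, rng)
    pixels = np.stack([_apply_noise(c + bg, rng) for c in chans[0]])[None]

    truth = SceneTruth(
        kind="two_cell",
        pixel_size=pixel_size,
        seed=seed,
        params={"pattern": pattern, "snr": snr, "axis_angle_deg": float(ang), "d_nn_um": d_nn_um},
        pattern={
            "shape": PATTERNS[pattern][0],
            "area_um2": PATTERNS[pattern][1],
            "center_xy_um": [0.0, 0.0],
        },
        nuclei=[{"center_xy_um": [float(c[0]), float(c[1])]} for c in nuc_centers],
        centrosomes=[{"center_xy_um": [float(c[0]), float(c[1])]} for c in cen_centers],
        ratio=float(d_nn_um / d_cc),
    )
    img = CalibratedImage(pixels=pixels, pixel_size=pixel_size, channels=dict(CELL_CHANNELS))
    return img, truth


# ---------------------------------------------------------------------------
# spheroid stacks
# ---------------------------------------------------------------------------

def _poisson_disk_directions(
    rng: np.random.Generator,
    n: int,
    min_angle_rad: float,
    keep_dot_below: float | None = None,
    cap_dir: np.ndarray | None = None,
) -> np.ndarray:
    """n well-separated unit vectors, optionally avoiding a spherical cap."""
    out: list[np.ndarray] = []
    min_cos = np.cos(min_angle_rad)
    tries = 0
    while len(out) < n:
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        tries += 1
        if tries > 20000:  # relax separation rather than loop forever
            min_cos = np.cos(np.arccos(min_cos) * 0.9)
            tries = 0
        if cap_dir is not None and keep_dot_below is not None and v @ cap_dir > keep_dot_below:
            continue
        if any(v @ w > min_cos for w in out):
            continue
        out.append(v)
    return np.array(out)


def make_spheroid(
    group: int,
    n_cells: int = 18,
    snr: float = 10.0,
    seed: int = 0,
    pixel_size: float = PIXEL_SIZE,
    z_step: float = Z_STEP,
    field_px: int = SPHEROID_FIELD_PX,
    n_planes: int = SPHEROID_PLANES,
    coverage_partial: float = 0.75,
) -> tuple[CalibratedImage, SceneTruth]:
    """Render a 4-channel spheroid z-stack of one of the five polarity phenotypes.

    group 1: closed cell shell, apical marker on the lumen-facing surface.
    group 2: as 1, but the shell is an open, partial sphere.
    group 3: solid cell ball, apical marker on the matrix-facing surface.
    group 4: as 3, partial (a cap of the ball is missing).
    group 5: irregular aggregate, several small cavities, mixed marker placement.
    """
    if group not in (1, 2, 3, 4, 5):
        raise ValueError("group must be in 1..5")
    if not 16 <= n_cells <= 20:
        raise ValueError("n_cells must be in 16..20")
    rng = np.random.default_rng(seed)

    r_out, r_in = 8.5, 5.5  # µm: outer shell radius and lumen radius
    center = np.array(
        [n_planes * z_step / 2, field_px * pixel_size / 2, field_px * pixel_size / 2]
    )
    z = np.arange(n_planes) * z_step
    yx = np.arange(field_px) * pixel_size
    dz = (z - center[0])[:, None, None]
    dy = (yx - center[1])[None, :, None]
    dx = (yx - center[2])[None, None, :]
    r = np.sqrt(dz**2 + dy**2 + dx**2)

    partial = group in (2, 4)
    coverage = coverage_partial if partial else 1.0
    cap_dir = rng.normal(size=3)
    cap_dir /= np.linalg.norm(cap_dir)
    # plane cut removing a cap of solid-angle fraction (1 - coverage)
    cut = r_out * (2 * coverage - 1)
    proj = dz * cap_dir[0] + dy * cap_dir[1] + dx * cap_dir[2]
    kept = proj < cut if partial else np.ones_like(r, dtype=bool)

    apical = np.zeros_like(r)
    baso = np.zeros_like(r)
    actin = np.zeros_like(r)
    cavities_truth: list[dict] = []

    if group in (1, 2):
        body = (r >= r_in) & (r <= r_out) & kept
        apical_band = (r >= r_in - 0.2) & (r <= r_in + 1.0) & kept
        baso_band = (r >= r_out - 1.0) & (r <= r_out) & kept
        nuc_radius, nuc_r = 1.4, (r_in + r_out) / 2
        dirs = _poisson_disk_directions(
            rng,
            n_cells,
            min_angle_rad=np.sqrt(4 * np.pi / n_cells) * 0.55,
            keep_dot_below=(cut / nuc_r - 0.25) if partial else None,
            cap_dir=cap_dir if partial else None,
        )
        nuclei_pos = center + nuc_r * dirs
        cavities_truth.append({"center_um": list(map(float, center)), "radius_um": r_in})
    elif group in (3, 4):
        body = (r <= r_out) & kept
        apical_band = (r >= r_out - 1.0) & (r <= r_out) & kept
        baso_band = (r <= r_out - 1.2) & kept
        nuc_radius = 1.4
        # nuclei through the volume, kept clear of the cut face and surface
        nuclei_pos = []
        tries = 0
        while len(nuclei_pos) < n_cells:
            tries += 1
            p = rng.uniform(-1, 1, 3) * (r_out - 2.0)
            if np.linalg.norm(p) > r_out - 2.0:
                continue
            if partial and p @ cap_dir > cut - 1.8:
                continue
            if any(np.linalg.norm(p - q) < 3.6 for q in nuclei_pos):
                if tries < 40000:
                    continue
            nuclei_pos.append(p)
        nuclei_pos = center + np.array(nuclei_pos)
    else:  # group 5: irregular aggregate
        # three overlapping lobes with well-separated centres
        while True:
            offsets = rng.normal(scale=2.5, size=(3, 3))
            offsets = np.clip(offsets, -3.5, 3.5)
            d01 = np.linalg.norm(offsets[0] - offsets[1])
            d02 = np.linalg.norm(offsets[0] - offsets[2])
            d12 = np.linalg.norm(offsets[1] - offsets[2])
            if all(6.6 <= d <= 8.2 for d in (d01, d02, d12)):
                break
        radii = rng.uniform(5.0, 6.0, size=3)
        body = np.zeros_like(r, dtype=bool)
        for off, rad in zip(offsets, radii):
            d = np.sqrt((dz - off[0]) ** 2 + (dy - off[1]) ** 2 + (dx - off[2]) ** 2)
            body |= d <= rad
        # carve 2-3 distinct small cavities, one per lobe centre
        n_cav = int(rng.integers(2, 4))
        for k in range(n_cav):
            off = offsets[k] + rng.normal(scale=0.3, size=3)
            d = np.sqrt((dz - off[0]) ** 2 + (dy - off[1]) ** 2 + (dx - off[2]) ** 2)
            cav = d <= 2.4
            body &= ~cav
            cavities_truth.append(
                {"center_um": list(map(float, center + off)), "radius_um": 2.4}
            )
            # apical on some cavity surfaces (mixed placement)
            if k % 2 == 0:
                apical += ((d > 2.4) & (d <= 3.4) & body) * 1.0
            else:
                baso += ((d > 2.4) & (d <= 3.4) & body) * 1.0
        # apical and basolateral patches on the outer surface as well
        d0 = np.sqrt((dz - offsets[0][0]) ** 2 + (dy - offsets[0][1]) ** 2 + (dx - offsets[0][2]) ** 2)
        outer_band0 = (d0 >= radii[0] - 1.0) & (d0 <= radii[0]) & body
        apical += outer_band0 * 1.0
        d1 = np.sqrt((dz - offsets[1][0]) ** 2 + (dy - offsets[1][1]) ** 2 + (dx - offsets[1][2]) ** 2)
        baso += ((d1 >= radii[1] - 1.0) & (d1 <= radii[1]) & body) * 1.0
        apical_band = None
        baso_band = None
        nuc_radius = 1.4
        nuclei_pos = []
        tries = 0
        zi = np.argwhere(body)
        while len(nuclei_pos) < n_cells and tries < 60000:
            tries += 1
            vox = zi[rng.integers(len(zi))]
            p = np.array([vox[0] * z_step, vox[1] * pixel_size, vox[2] * pixel_size])
            if any(np.linalg.norm(p - q) < 3.4 for q in nuclei_pos):
                continue
            nuclei_pos.append(p)
        nuclei_pos = np.array(nuclei_pos)

    if group != 5:
        apical = apical_band.astype(float)
        baso = baso_band.astype(float)
    actin = body.astype(float) * 0.5 + apical * 0.6

    nuc_img = np.zeros_like(r)
    for p in nuclei_pos:
        d = np.sqrt((dz - (p[0] - center[0])) ** 2 + (dy - (p[1] - center[1])) ** 2 + (dx - (p[2] - center[2])) ** 2)
        nuc_img = np.maximum(nuc_img, d <= nuc_radius)

    amp = snr * np.sqrt(60.0 + READ_NOISE_SD**2)
    sigma = (0.3 / z_step, PSF_SIGMA_UM / pixel_size, PSF_SIGMA_UM / pixel_size)
    stack = np.zeros((n_planes, 4, field_px, field_px))
    stack[:, SPHEROID_CHANNELS["nucleus"]] = ndi.gaussian_filter(nuc_img * amp, sigma)
    stack[:, SPHEROID_CHANNELS["actin"]] = ndi.gaussian_filter(actin * amp * 0.7, sigma)
    stack[:, SPHEROID_CHANNELS["apical"]] = ndi.gaussian_filter(apical * amp, sigma)
    stack[:, SPHEROID_CHANNELS["basolateral"]] = ndi.gaussian_filter(baso * amp, sigma)

    bg2d = _background_field((field_px, field_px), rng, level=60.0, gradient=10.0)
    out = np.empty_like(stack, dtype=np.uint16)
    for c in range(4):
        out[:, c] = _apply_noise(stack[:, c] + bg2d[None], rng)

    truth = SceneTruth(
        kind="spheroid",
        pixel_size=pixel_size,
        z_step=z_step,
        seed=seed,
        params={
            "snr": snr,
            "coverage": coverage,
            "cap_dir": list(map(float, cap_dir)),
            "r_out_um": r_out,
            "r_in_um": r_in,
            "cavities": cavities_truth,
        },
        group=group,
        n_cells=int(len(nuclei_pos)),
        nuclei=[{"center_um": list(map(float, p))} for p in nuclei_pos],
    )
    img = CalibratedImage(
        pixels=out, pixel_size=pixel_size, z_step=z_step, channels=dict(SPHEROID_CHANNELS)
    )
    return img, truth


# ---------------------------------------------------------------------------
# qPCR and blot tables
# ---------------------------------------------------------------------------

REFERENCE_GENES = ("Gapdh", "Ubb", "B2M", "Hprt")
_BASE_CT = {"Pkhd1": 26.0, "Gapdh": 18.0, "Ubb": 20.0, "B2M": 22.0, "Hprt": 24.0}


def make_qpcr_table(
    true_knockdown_fraction: float = 0.25,
    n_refs: int = 4,
    ct_noise_sd: float = 0.15,
    seed: int = 0,
    n_replicates: int = 3,
    target_gene: str = "Pkhd1",
    unstable_ref: str | None = "B2M",
    unstable_shift: float = 0.8,
) -> pd.DataFrame:
    """CT table (sample, gene, replicate, ct) with a planted expression ratio.

    The treated sample's target CT is shifted by −log2(fraction) cycles.  One
    reference gene can be made condition-unstable (a treated-only CT shift) to
    exercise the 3-of-4 reference selection.
    """
    if not 0 < true_knockdown_fraction <= 1:
        raise ValueError("true_knockdown_fraction must be in (0, 1]")
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    refs = REFERENCE_GENES[:n_refs]
    rows = []
    for sample in ("control", "treated"):
        for gene in (target_gene, *refs):
            base = _BASE_CT.get(gene, 25.0)
            ct = base
            if sample == "treated" and gene == target_gene:
                ct += -np.log2(true_knockdown_fraction)
            if sample == "treated" and gene == unstable_ref:
                ct += unstable_shift
            for rep in range(n_replicates):
                rows.append(
                    {
                        "sample": sample,
                        "gene": gene,
                        "replicate": rep + 1,
                        "ct": float(ct + rng.normal(0, ct_noise_sd)),
                    }
                )
    return pd.DataFrame(rows)


def make_blot_table(
    true_ratio: float = 0.5,
    intensity_noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Band-intensity table (lane, band, intensity) with a planted treated/control ratio."""
    rng = np.random.default_rng(seed)
    base = {"target": 1000.0, "vinculin": 800.0, "myosin": 600.0}
    rows = []
    for lane, scale in (("control", 1.0), ("treated", true_ratio)):
        load = rng.uniform(0.8, 1.2)  # lane-to-lane loading variation
        for band, level in base.items():
            val = level * load * (scale if band == "target" else 1.0)
            val *= 1 + rng.normal(0, intensity_noise_cv) if intensity_noise_cv else 1.0
            rows.append({"lane": lane, "band": band, "intensity": float(val)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# writing scenes to disk
# ---------------------------------------------------------------------------

def write_scene(
    img: CalibratedImage, truth: SceneTruth, directory: str | Path, stem: str
) -> tuple[Path, Path]:
    """Write an OME-TIFF plus its JSON ground-truth sidecar."""
    from micromorph.io_core import write_image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tif = directory / f"{stem}.ome.tif"
    sidecar = directory / f"{stem}.truth.json"
    write_image(tif, img)
    truth.to_json(sidecar)
    return tif, sidecar
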