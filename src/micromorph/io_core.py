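"""Calibrated image and configuration containers, TIFF/OME-TIFF I/O, result tables.

All pixel data are held in a fixed ``(z, channel, y, x)`` axis order with an
explicit lateral calibration in micrometres per pixel.  Channels are addressed
by *role* (``vinculin``, ``actin``, ``nucleus``, ``centrosome``, ``pattern``,
``apical``, ``basolateral``), never by positional convention, because the
stain-to-channel assignment differs between assays.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger(__name__)

#: Channel roles understood by the analysis stages.
CHANNEL_ROLES = (
    "vinculin",
    "actin",
    "nucleus",
    "centrosome",
    "pattern",
    "apical",
    "basolateral",
)


class CalibrationError(ValueError):
    """Raised when pixel calibration is missing or invalid."""


@dataclass
class CalibratedImage:
    """A multi-channel fluorescence image (optionally a z-stack) with physical calibration.

    Parameters
    ----------
    pixels
        Intensity array indexed ``(z, channel, y, x)``; ``z`` may be singleton.
    pixel_size
        Lateral sampling in µm/px (> 0).
    channels
        Mapping from channel role to channel index.
    z_step
        Axial spacing in µm; required whenever ``z > 1``.
    """

    pixels: np.ndarray
    pixel_size: float
    channels: Mapping[str, int]
    z_step: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ValueError(
                f"pixels must be (z, channel, y, x); got shape {self.pixels.shape}"
            )
        if not self.pixel_size > 0:
            raise CalibrationError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.nz > 1 and (self.z_step is None or not self.z_step > 0):
            raise CalibrationError("z_step (> 0) is required for z-stacks")
        if np.any(np.asarray(self.pixels) < 0):
            raise ValueError("intensities must be non-negative")
        for role, idx in self.channels.items():
            if role not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {role!r}; valid: {CHANNEL_ROLES}")
            if not 0 <= idx < self.n_channels:
                raise ValueError(
                    f"channel role {role!r} maps to index {idx}, but image has "
                    f"{self.n_channels} channels"
                )

    @property
    def nz(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.pixels.shape[2], self.pixels.shape[3]

    def has_role(self, role: str) -> bool:
        return role in self.channels

    def require_roles(self, roles: Sequence[str]) -> None:
        missing = [r for r in roles if r not in self.channels]
        if missing:
            raise KeyError(f"image lacks required channel roles: {missing}")

    def channel(self, role: str) -> np.ndarray:
        """Return the full (z, y, x) stack of one channel role."""
        return self.pixels[:, self.channels[role]]

    def plane(self, role: str, z: int = 0) -> np.ndarray:
        """Return a single (y, x) plane of one channel role."""
        return self.pixels[z, self.channels[role]]

    def max_project(self, role: str) -> np.ndarray:
        """Maximum-intensity projection of a channel along z.

        This is the named projection step used before nucleus/centrosome
        detection; it is a no-op for single-plane images.
        """
        if self.nz > 1:
            logger.info("max-intensity projection of role %r over %d planes", role, self.nz)
        return self.channel(role).max(axis=0)


@dataclass
class AssayConfig:
    """Analysis configuration shared by all stages.

    Defaults encode the assay conventions: adhesion sites below 0.1 µm² are
    discarded, and cells smaller than 400 µm² or covering less than one third
    of the pattern are excluded from single-cell analyses.
    """

    pattern_shape: str = "disc"  # {disc, crossbow}
    pattern_area: float = 700.0  # µm², one of {700, 1100, 1600}
    min_adhesion_area: float = 0.1  # µm²
    min_cell_area: float = 400.0  # µm²
    min_pattern_cover_fraction: float = 1.0 / 3.0
    threshold_method: str | float = "otsu"  # "otsu" or a fixed intensity value
    rolling_ball_radius: float = 5.0  # µm
    nucleus_area_range: tuple[float, float] = (20.0, 400.0)  # µm², 2D projected
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern_shape not in ("disc", "crossbow"):
            raise ValueError(f"pattern_shape must be disc or crossbow, got {self.pattern_shape!r}")
        for name in ("pattern_area", "min_adhesion_area", "min_cell_area", "rolling_ball_radius"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.min_pattern_cover_fraction <= 1:
            raise ValueError("min_pattern_cover_fraction must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AssayConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "nucleus_area_range" in data:
            data["nucleus_area_range"] = tuple(data["nucleus_area_range"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["nucleus_area_range"] = list(d["nucleus_area_range"])
        return d


# ---------------------------------------------------------------------------
# Image I/O
# ---------------------------------------------------------------------------

def _normalize_axes(data: np.ndarray, axes: str) -> np.ndarray:
    """Reorder a tifffile series to (z, c, y, x), inserting singleton axes."""
    axes = axes.upper()
    # tifffile labels unidentified axes 'Q' (and samples 'S'); map a non-trivial
    # unknown axis to the first of C, Z that is still free
    for i, ax in enumerate(axes):
        if ax in "QSI" and data.shape[i] > 1:
            for cand in "CZ":
                if cand not in axes:
                    axes = axes[:i] + cand + axes[i + 1 :]
                    break
    # drop axes that are neither Z, C, Y nor X (e.g. T or S of length 1)
    for i, ax in reversed(list(enumerate(axes))):
        if ax not in "ZCYX":
            if data.shape[i] != 1:
                raise ValueError(f"cannot interpret axis {ax!r} of length {data.shape[i]}")
            data = data.squeeze(axis=i)
            axes = axes[:i] + axes[i + 1 :]
    out = data
    for target_pos, ax in enumerate("ZCYX"):
        if ax not in axes:
            out = np.expand_dims(out, target_pos)
            axes = axes[:target_pos] + ax + axes[target_pos:]
        else:
            cur = axes.index(ax)
            if cur != target_pos:
                out = np.moveaxis(out, cur, target_pos)
                axes = axes.replace(ax, "")
                axes = axes[:target_pos] + ax + axes[target_pos:]
    return out


def _ome_pixel_size(tif: tifffile.TiffFile) -> tuple[float | None, float | None]:
    """Extract (pixel_size_um, z_step_um) from OME metadata, if present."""
    if not tif.ome_metadata:
        return None, None
    try:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tif.ome_metadata)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        px = root.find(".//ome:Pixels", ns)
        if px is None:
            return None, None
        sx = px.get("PhysicalSizeX")
        sz = px.get("PhysicalSizeZ")
        return (float(sx) if sx else None, float(sz) if sz else None)
    except Exception:  # malformed metadata: treat as absent
        return None, None


def read_image(
    path: str | Path,
    channel_map: Mapping[str, int],
    pixel_size: float | None = None,
    z_step: float | None = None,
) -> CalibratedImage:
    """Read a TIFF/OME-TIFF into a :class:`CalibratedImage`.

    OME physical pixel sizes, when present, provide the calibration unless an
    explicit ``pixel_size``/``z_step`` override is given.  Missing calibration
    is a hard error — the analyses are meaningless without physical units.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        meta_px, meta_z = _ome_pixel_size(tif)
    pixels = _normalize_axes(data, axes)
    px = pixel_size if pixel_size is not None else meta_px
    zs = z_step if z_step is not None else meta_z
    if px is None:
        raise CalibrationError(
            f"{path}: no pixel size in metadata and no override given; "
            "calibration must always be explicit"
        )
    if pixels.shape[0] > 1 and zs is None:
        raise CalibrationError(f"{path}: z-stack without z-step calibration")
    return CalibratedImage(pixels=pixels, pixel_size=px, channels=dict(channel_map), z_step=zs)


def write_image(
    path: str | Path,
    img: CalibratedImage,
) -> None:
    """Write a :class:`CalibratedImage` as OME-TIFF with physical pixel sizes."""
    meta = {
        "axes": "ZCYX",
        "PhysicalSizeX": img.pixel_size,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": img.pixel_size,
        "PhysicalSizeYUnit": "µm",
    }
    if img.z_step is not None:
        meta["PhysicalSizeZ"] = img.z_step
        meta["PhysicalSizeZUnit"] = "µm"
    tifffile.imwrite(str(path), img.pixels, ome=True, metadata=meta)


# ---------------------------------------------------------------------------
# Tabular results
# ---------------------------------------------------------------------------

def write_results(
    records: pd.DataFrame,
    path: str | Path,
    config: AssayConfig | None = None,
    units: Mapping[str, str] | None = None,
    allow_empty: bool = False,
) -> None:
    """Write a result table as CSV plus a JSON sidecar with provenance.

    The CSV starts with ``#``-prefixed comment lines documenting column units;
    the sidecar records the configuration and software version.
    """
    from micromorph import __version__

    path = Path(path)
    if len(records) == 0 and not allow_empty:
        raise ValueError("refusing to write empty result table (pass allow_empty=True)")
    with open(path, "w") as fh:
        if units:
            for col, unit in units.items():
                fh.write(f"# {col}: {unit}\n")
        records.to_csv(fh, index=False)
    sidecar = {
        "software": "micromorph",
        "version": __version__,
        "n_records": int(len(records)),
        "columns": list(records.columns),
        "config": config.to_dict() if config is not None else None,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_results`, skipping unit comments."""
    return pd.read_csv(path, comment="#")
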