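"""Multiband raster I/O, radiometric calibration, and plot extraction.

Conventions: pixels are addressed by 0-based (row, col); each pixel covers
the half-open square [col, col+1) x [row, row+1) in (x, y) = (col, row)
coordinates, with its center at (col + 0.5, row + 0.5).  ROI membership is
pixel-center-in-polygon.  Rasters are stored as multiband TIFF with the band
registry embedded as JSON in the image description, so a round trip
preserves both pixels and band identity.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import box, shape as geo_shape
from shapely.geometry.base import BaseGeometry

from .bands import Band, band_index, registry_from_names, registry_to_names
from .errors import EmptyROIError, StackFormatError

_REFLECTANCE_MAX = 1.5  # tolerates slight calibration overshoot


@dataclass
class BandStack:
    """A (rows, cols, bands) image plus its band registry.

    ``units`` is ``"reflectance"`` (values in [0, 1.5]) or ``"dn"`` (raw
    sensor digital numbers awaiting calibration).
    """

    pixels: np.ndarray
    band_registry: tuple[Band, ...]
    units: str = "reflectance"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise StackFormatError(
                f"pixels must be (rows, cols, bands), got shape {self.pixels.shape}"
            )
        self.band_registry = tuple(self.band_registry)
        if self.pixels.shape[2] != len(self.band_registry):
            raise StackFormatError(
                f"raster has {self.pixels.shape[2]} bands but the registry "
                f"declares {len(self.band_registry)}"
            )
        if self.units not in ("reflectance", "dn"):
            raise StackFormatError(f"unknown units {self.units!r}")
        if self.units == "reflectance":
            finite = self.pixels[np.isfinite(self.pixels)]
            if finite.size and (finite.min() < 0 or finite.max() > _REFLECTANCE_MAX):
                raise StackFormatError(
                    "reflectance values outside [0, 1.5]; is this a DN stack?"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def band(self, center: int) -> np.ndarray:
        """2-D view of the band with the given center wavelength (nm)."""
        return self.pixels[:, :, band_index(self.band_registry, center)]


def write_stack(stack: BandStack, path) -> Path:
    """Write a stack as a multiband TIFF with the registry in the description."""
    path = Path(path)
    meta = {
        "bands": registry_to_names(stack.band_registry),
        "units": stack.units,
    }
    tifffile.imwrite(
        path,
        np.ascontiguousarray(np.moveaxis(stack.pixels, 2, 0)),
        photometric="minisblack",
        description=json.dumps(meta),
    )
    return path


def read_stack(path, registry: Sequence[Band] | None = None,
               units: str | None = None) -> BandStack:
    """Read a multiband TIFF.

    The band registry is taken from the file's embedded metadata; an explicit
    *registry* overrides it and must match the file's band count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster not found: {path}")
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].description
    if arr.ndim == 2:
        arr = arr[None, :, :]
    pixels = np.moveaxis(arr, 0, 2).astype(float)

    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if registry is None:
        if "bands" not in meta:
            raise StackFormatError(
                f"{path} carries no band metadata; pass an explicit registry"
            )
        registry = registry_from_names(meta["bands"])
    registry = tuple(registry)
    if len(registry) != pixels.shape[2]:
        raise StackFormatError(
            f"{path} has {pixels.shape[2]} bands but the declared registry "
            f"has {len(registry)}"
        )
    return BandStack(pixels, registry, units or meta.get("units", "reflectance"))


def calibrate(
    dn_stack: BandStack,
    panel_dn: Sequence[float],
    panel_reflectance: Sequence[float],
) -> BandStack:
    """Single-panel zero-intercept radiometric calibration.

    Per band: reflectance = DN * (panel_reflectance / panel_dn), the standard
    one-point gain from a gray reference panel of known reflectance.
    """
    if dn_stack.units != "dn":
        raise ValueError("calibrate expects a stack in DN units")
    panel_dn = np.asarray(panel_dn, dtype=float)
    panel_reflectance = np.asarray(panel_reflectance, dtype=float)
    nb = len(dn_stack.band_registry)
    if panel_dn.shape != (nb,) or panel_reflectance.shape != (nb,):
        raise ValueError(f"panel readings must have one value per band ({nb})")
    if np.any(panel_dn <= 0):
        raise ValueError("panel DN values must be strictly positive")
    gain = panel_reflectance / panel_dn
    return BandStack(dn_stack.pixels * gain, dn_stack.band_registry, "reflectance")


# ---------------------------------------------------------------------------
# Regions of interest

def load_rois(path) -> dict[str, BaseGeometry]:
    """Load plot ROIs keyed by plot_id.

    GeoJSON (``.geojson``/``.json``): a FeatureCollection of polygons with a
    ``plot_id`` property, coordinates in pixel space (x = col, y = row).
    CSV: columns ``plot_id,row_min,row_max,col_min,col_max`` with half-open
    pixel ranges.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ROI file not found: {path}")
    if path.suffix.lower() in (".geojson", ".json"):
        payload = json.loads(path.read_text())
        rois = {}
        for feat in payload["features"]:
            pid = str(feat["properties"]["plot_id"])
            rois[pid] = geo_shape(feat["geometry"])
        return rois
    df = pd.read_csv(path)
    required = {"plot_id", "row_min", "row_max", "col_min", "col_max"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ROI CSV missing columns: {sorted(missing)}")
    return {
        str(r.plot_id): box(r.col_min, r.row_min, r.col_max, r.row_max)
        for r in df.itertuples()
    }


def roi_mask(shape: tuple[int, int], roi: BaseGeometry) -> np.ndarray:
    """Boolean (rows, cols) mask of pixels whose centers fall inside *roi*."""
    rows, cols = shape
    minx, miny, maxx, maxy = roi.bounds
    c0 = max(0, int(np.floor(minx)))
    c1 = min(cols, int(np.ceil(maxx)))
    r0 = max(0, int(np.floor(miny)))
    r1 = min(rows, int(np.ceil(maxy)))
    mask = np.zeros(shape, dtype=bool)
    if c1 <= c0 or r1 <= r0:
        return mask
    xs = np.arange(c0, c1) + 0.5
    ys = np.arange(r0, r1) + 0.5
    X, Y = np.meshgrid(xs, ys)
    mask[r0:r1, c0:c1] = shapely.contains_xy(roi, X, Y)
    return mask


def extract_plot_pixels(
    stack: BandStack, roi: BaseGeometry, plot_id: str | None = None
) -> np.ndarray:
    """Pixels (n_pixels, bands) whose centers fall inside *roi*."""
    mask = roi_mask(stack.shape, roi)
    if not mask.any():
        name = f" for plot {plot_id}" if plot_id else ""
        raise EmptyROIError(f"ROI{name} selects no pixels in a "
                            f"{stack.shape[0]}x{stack.shape[1]} raster")
    return stack.pixels[mask]


def plot_mean_reflectance(pixel_matrix: np.ndarray) -> np.ndarray:
    """Arithmetic per-band mean over a (n_pixels, bands) matrix."""
    pixel_matrix = np.asarray(pixel_matrix, dtype=float)
    if pixel_matrix.ndim != 2 or pixel_matrix.shape[0] == 0:
        raise EmptyROIError("pixel matrix must be non-empty (n_pixels, bands)")
    return pixel_matrix.mean(axis=0)


def band_mean_table(
    stack: BandStack, rois: Mapping[str, BaseGeometry]
) -> pd.DataFrame:
    """Per-plot mean reflectance table with one ``b<wavelength>`` column per band."""
    cols = [b.column for b in stack.band_registry]
    records = []
    for pid, roi in rois.items():
        means = plot_mean_reflectance(extract_plot_pixels(stack, roi, pid))
        records.append({"plot_id": pid, **dict(zip(cols, means))})
    return pd.DataFrame.from_records(records, columns=["plot_id", *cols])
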