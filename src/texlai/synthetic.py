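"""Synthetic multispectral plot scenes with known leaf area index.

The generator emulates a plot-trial campaign: ``n_plots`` field plots imaged
on ``n_dates`` acquisition dates, each plot a small multiband reflectance
image plus a ground-truth LAI value.  Reflectance follows a two-endmember
Beer-Lambert mixing model,

    R_b(LAI) = soil_b * exp(-k_b * LAI) + leaf_b * (1 - exp(-k_b * LAI)),

so every band is a monotone function of LAI: visible bands darken as canopy
closes over bright soil, NIR brightens.  Spatial texture arises from a
correlated canopy-gap field whose gap fraction equals exp(-k_ref * LAI) for
the NIR reference band; pixels are soil inside gaps and a per-band canopy
endmember elsewhere, chosen so the image mean reproduces R_b(LAI) exactly
before sensor noise.  Additive Gaussian noise models the sensor.

This is a statistical stand-in, not a radiative-transfer model: no BRDF,
no row structure, no variety-specific spectra.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date as _date
from datetime import timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .bands import REDEDGE_MX_DUAL, Band, band_index, registry_to_names

# Default endmember spectra over the ten-band registry (444..842 nm).
# Soil: slowly brightening with wavelength. Leaf: low visible reflectance
# with a green bump, sharp red-edge rise between 717 and 740 nm, bright NIR.
_DEFAULT_SOIL = np.array(
    [0.100, 0.114, 0.139, 0.152, 0.193, 0.201, 0.218, 0.223, 0.234, 0.280]
)
_DEFAULT_LEAF = np.array(
    [0.040, 0.040, 0.100, 0.120, 0.050, 0.050, 0.150, 0.200, 0.380, 0.480]
)
# Extinction: strong absorption in the visible, weaker scattering-dominated
# attenuation towards the NIR.
_DEFAULT_EXTINCTION = np.array(
    [0.80, 0.80, 0.80, 0.80, 0.80, 0.80, 0.70, 0.70, 0.70, 0.60]
)

#: Acquisition dates mimic a late-July to early-September campaign.
_BASE_DATE = _date(2021, 7, 24)
_DATE_SPACING_DAYS = 11


@dataclass
class CanopyParams:
    """Configuration of the synthetic canopy and campaign.

    Reflectances are unitless in [0, 1]; ``extinction`` is the per-band
    Beer-Lambert coefficient (per unit LAI); ``gap_scale`` is the spatial
    correlation length of canopy gaps in pixels; ``noise_sd`` the additive
    sensor noise in reflectance units.
    """

    soil_reflectance: np.ndarray = field(default_factory=_DEFAULT_SOIL.copy)
    leaf_reflectance: np.ndarray = field(default_factory=_DEFAULT_LEAF.copy)
    extinction: np.ndarray = field(default_factory=_DEFAULT_EXTINCTION.copy)
    gap_scale: float = 4.0
    noise_sd: float = 0.005
    n_plots: int = 140
    n_dates: int = 5
    plot_size: tuple[int, int] = (64, 64)
    lai_range: tuple[float, float] = (0.5, 5.5)
    seed: int = 0
    registry: tuple[Band, ...] = REDEDGE_MX_DUAL

    def __post_init__(self) -> None:
        self.soil_reflectance = np.asarray(self.soil_reflectance, dtype=float)
        self.leaf_reflectance = np.asarray(self.leaf_reflectance, dtype=float)
        self.extinction = np.asarray(self.extinction, dtype=float)
        nb = len(self.registry)
        for name in ("soil_reflectance", "leaf_reflectance", "extinction"):
            arr = getattr(self, name)
            if arr.shape != (nb,):
                raise ValueError(f"{name} must have {nb} entries, got {arr.shape}")
        for name in ("soil_reflectance", "leaf_reflectance"):
            arr = getattr(self, name)
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if np.any(self.extinction <= 0):
            raise ValueError("extinction must be strictly positive per band")
        i_nir = band_index(self.registry, 842)
        i_red = band_index(self.registry, 650)
        if not self.leaf_reflectance[i_nir] > self.soil_reflectance[i_nir]:
            raise ValueError("leaf NIR reflectance must exceed soil NIR reflectance")
        if not self.leaf_reflectance[i_red] < self.soil_reflectance[i_red]:
            raise ValueError("leaf red reflectance must be below soil red reflectance")
        if self.n_plots < 1 or self.n_dates < 1:
            raise ValueError("n_plots and n_dates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        _check_lai_range(self.lai_range)

    @property
    def n_bands(self) -> int:
        return len(self.registry)

    @property
    def reference_band_index(self) -> int:
        """Index of the NIR band whose extinction defines the gap fraction."""
        return band_index(self.registry, 842)


def _check_lai_range(lai_range: Sequence[float]) -> tuple[float, float]:
    lo, hi = float(lai_range[0]), float(lai_range[1])
    if not (0 <= lo < hi):
        raise ValueError(f"lai_range must satisfy 0 <= min < max, got {(lo, hi)}")
    return lo, hi


def phenology_profile(n_dates: int) -> np.ndarray:
    """Rise-and-fall canopy development weight per date, in (0, 1]."""
    d = np.arange(1, n_dates + 1)
    return np.sin(np.pi * d / (n_dates + 1))


def sample_lai(
    n_plots: int,
    n_dates: int,
    lai_range: tuple[float, float],
    seed: int,
) -> np.ndarray:
    """Draw a (n_plots, n_dates) matrix of ground-truth LAI values.

    Each plot carries a persistent "variety" vigour factor; dates follow a
    rise-and-fall phenology profile (emergence of tassels through milk
    ripening), with multiplicative lognormal-ish jitter.  Values are strictly
    inside ``lai_range``.
    """
    if n_plots < 1 or n_dates < 1:
        raise ValueError("n_plots and n_dates must be >= 1")
    lo, hi = _check_lai_range(lai_range)
    rng = np.random.default_rng(seed)
    profile = phenology_profile(n_dates)  # (n_dates,)
    vigour = rng.uniform(0.55, 1.0, size=n_plots)  # plot/variety effect
    jitter = rng.normal(1.0, 0.06, size=(n_plots, n_dates))
    frac = np.clip(vigour[:, None] * profile[None, :] * jitter, 0.02, 0.98)
    return lo + (hi - lo) * frac


def canopy_reflectance(lai, params: CanopyParams) -> np.ndarray:
    """Expected per-band reflectance of a canopy with the given LAI.

    ``lai`` may be a scalar or an array; the band axis is appended last.
    """
    lai = np.asarray(lai, dtype=float)
    if np.any(lai < 0):
        raise ValueError("lai must be non-negative")
    atten = np.exp(-np.multiply.outer(lai, params.extinction))
    return params.soil_reflectance * atten + params.leaf_reflectance * (1.0 - atten)


def _gap_mask(shape: tuple[int, int], gap_fraction: float, gap_scale: float,
              rng: np.random.Generator) -> np.ndarray:
    """Boolean mask (True = soil gap) with the exact requested gap count."""
    n = shape[0] * shape[1]
    k = int(round(gap_fraction * n))
    if k <= 0:
        return np.zeros(shape, dtype=bool)
    if k >= n:
        return np.ones(shape, dtype=bool)
    noise = rng.standard_normal(shape)
    smooth = gaussian_filter(noise, sigma=gap_scale, mode="reflect")
    order = np.argsort(smooth, axis=None, kind="stable")
    mask = np.zeros(n, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(shape)


def render_plot_image(lai: float, params: CanopyParams, seed) -> np.ndarray:
    """Render one plot as a (rows, cols, bands) reflectance image.

    Gaps show bare soil; canopy pixels take a per-band endmember chosen so
    that the noise-free image mean equals ``canopy_reflectance(lai)``.
    """
    if lai < 0:
        raise ValueError("lai must be non-negative")
    rng = np.random.default_rng(seed)
    rows, cols = params.plot_size
    k_ref = params.extinction[params.reference_band_index]
    gap_fraction = float(np.exp(-k_ref * lai))
    gaps = _gap_mask((rows, cols), gap_fraction, params.gap_scale, rng)
    g_actual = gaps.mean()

    target = canopy_reflectance(lai, params)  # (bands,)
    img = np.empty((rows, cols, params.n_bands), dtype=float)
    img[gaps] = params.soil_reflectance
    if g_actual < 1.0:
        canopy_value = (target - g_actual * params.soil_reflectance) / (1.0 - g_actual)
        img[~gaps] = canopy_value
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def acquisition_dates(n_dates: int) -> list[str]:
    """ISO date labels for the campaign (11-day spacing from late July)."""
    return [
        (_BASE_DATE + timedelta(days=_DATE_SPACING_DAYS * d)).isoformat()
        for d in range(n_dates)
    ]


def _plot_grid(n_plots: int, plot_size: tuple[int, int], margin: int):
    """Tile layout: (grid_cols, origin list [(row0, col0)], scene shape)."""
    grid_cols = int(np.ceil(np.sqrt(n_plots)))
    grid_rows = int(np.ceil(n_plots / grid_cols))
    ph, pw = plot_size
    origins = []
    for p in range(n_plots):
        tr, tc = divmod(p, grid_cols)
        origins.append((margin + tr * (ph + margin), margin + tc * (pw + margin)))
    shape = (
        margin + grid_rows * (ph + margin),
        margin + grid_cols * (pw + margin),
    )
    return origins, shape


def plot_id(p: int) -> str:
    return f"plot_{p + 1:03d}"


def generate_dataset(params: CanopyParams, out_dir) -> dict:
    """Write a full synthetic campaign to ``out_dir``.

    Outputs one multiband TIFF per acquisition date (plots tiled on a soil
    background grid), ``rois.geojson`` with one pixel-space polygon per plot
    (inset 2 px from the tile edge so plot-boundary windows never mix
    plots), and ``plots.csv`` with columns ``plot_id,date,lai``.

    Returns a manifest dict with the written paths and the LAI matrix.
    """
    from . import raster  # deferred: raster imports tifffile

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    margin, inset = 4, 2
    lai = sample_lai(params.n_plots, params.n_dates, params.lai_range, params.seed)
    dates = acquisition_dates(params.n_dates)
    origins, scene_shape = _plot_grid(params.n_plots, params.plot_size, margin)
    ph, pw = params.plot_size

    ss = np.random.SeedSequence(params.seed)
    plot_seeds = ss.spawn(params.n_plots * params.n_dates)
    bg_seeds = ss.spawn(params.n_dates)

    raster_paths = []
    for d, date_str in enumerate(dates):
        scene = np.empty(scene_shape + (params.n_bands,), dtype=float)
        scene[:] = params.soil_reflectance
        bg_rng = np.random.default_rng(bg_seeds[d])
        if params.noise_sd > 0:
            scene += bg_rng.normal(0.0, params.noise_sd, size=scene.shape)
            scene = np.clip(scene, 0.0, 1.0)
        for p in range(params.n_plots):
            r0, c0 = origins[p]
            tile = render_plot_image(
                lai[p, d], params, plot_seeds[p * params.n_dates + d]
            )
            scene[r0 : r0 + ph, c0 : c0 + pw] = tile
        path = out_dir / f"reflectance_{date_str}.tif"
        raster.write_stack(
            raster.BandStack(scene.astype(np.float32), params.registry, "reflectance"),
            path,
        )
        raster_paths.append(path)

    features = []
    for p in range(params.n_plots):
        r0, c0 = origins[p]
        x0, y0 = c0 + inset, r0 + inset
        x1, y1 = c0 + pw - inset, r0 + ph - inset
        features.append(
            {
                "type": "Feature",
                "properties": {"plot_id": plot_id(p)},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [
                        [[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]
                    ],
                },
            }
        )
    roi_path = out_dir / "rois.geojson"
    roi_path.write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )

    csv_path = out_dir / "plots.csv"
    lines = ["plot_id,date,lai"]
    for p in range(params.n_plots):
        for d, date_str in enumerate(dates):
            lines.append(f"{plot_id(p)},{date_str},{lai[p, d]:.6f}")
    csv_path.write_text("\n".join(lines) + "\n")

    return {
        "rasters": {dates[d]: raster_paths[d] for d in range(params.n_dates)},
        "rois": roi_path,
        "lai_table": csv_path,
        "lai": lai,
        "dates": dates,
    }
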