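"""Gray-level co-occurrence texture features.

A band image is linearly quantized to ``levels`` gray levels over its full
range, then for every interior pixel a GLCM is accumulated from all pixel
pairs inside its centered window at the configured offsets.  Counts from all
offsets are pooled into a single matrix (equivalently, the per-offset GLCMs
are averaged with weights proportional to their pair counts), symmetrized by
adding the transpose when ``symmetric``, and normalized to sum 1.  Eight
Haralick-style statistics summarize each window GLCM:

    mean  = sum_i i * P_i(i)                 (reference-marginal mean)
    var   = sum_i (i - mean)^2 * P_i(i)
    hom   = sum_ij P(i,j) / (1 + (i-j)^2)    (homogeneity / IDM)
    con   = sum_ij (i-j)^2 * P(i,j)          (contrast)
    dis   = sum_ij |i-j| * P(i,j)            (dissimilarity)
    ent   = -sum_{P>0} P * ln P              (entropy, natural log)
    sm    = sum_ij P(i,j)^2                  (second/angular moment)
    cor   = sum_ij (i-mu_i)(j-mu_j) P / (sigma_i sigma_j), 0 if degenerate

Plot-level texture features are the means of these statistic maps over the
plot ROI, named ``{stat}_{band}`` (e.g. ``mean_705``, ``ent_842``).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .errors import DomainError, EmptyROIError
from .bands import TEXTURE_BANDS

STAT_NAMES: tuple[str, ...] = (
    "mean", "var", "hom", "con", "dis", "ent", "sm", "cor",
)

#: Unit displacements covering the four GLCM directions (0, 45, 90, 135 deg
#: up to the symmetrizing transpose).
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (1, 1), (1, 0), (1, -1))


@dataclass
class GLCMConfig:
    """Texture-extraction settings (ENVI-style occurrence defaults)."""

    levels: int = 64
    window: int = 3
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS
    symmetric: bool = True
    bands: tuple[int, ...] = TEXTURE_BANDS

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        self.offsets = tuple((int(a), int(b)) for a, b in self.offsets)
        if not self.offsets or any(o == (0, 0) for o in self.offsets):
            raise ValueError("offsets must be non-empty and non-zero")
        mx = self.window - 1
        if any(abs(a) > mx or abs(b) > mx for a, b in self.offsets):
            raise ValueError("offset exceeds window extent")
        self.bands = tuple(int(b) for b in self.bands)


def quantize(band_raster: np.ndarray, levels: int) -> np.ndarray:
    """Linear min-max quantization to integer levels {0, ..., levels-1}.

    The raster minimum maps to 0 and the maximum to levels-1; a constant
    raster maps entirely to level 0.  Quantization is over the full raster
    (not per window) so gray levels are comparable across plots.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    arr = np.asarray(band_raster, dtype=float)
    finite = np.isfinite(arr)
    if not finite.any():
        raise ValueError("cannot quantize an all-NaN raster")
    lo = arr[finite].min()
    hi = arr[finite].max()
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.int32)
    q = np.floor((arr - lo) / (hi - lo) * levels)
    q = np.clip(q, 0, levels - 1)
    out = q.astype(np.int32)
    out[~finite] = -1  # invalid marker; excluded from pair counting
    return out


def glcm(
    window_pixels: np.ndarray,
    offset: tuple[int, int] | Sequence[tuple[int, int]],
    levels: int,
    symmetric: bool = True,
) -> np.ndarray:
    """Co-occurrence probability matrix of one quantized window.

    *offset* may be a single (drow, dcol) displacement or a sequence of
    them; counts from several offsets are pooled before normalization.
    Raises :class:`DomainError` if no valid pixel pair exists.
    """
    q = np.asarray(window_pixels)
    if q.ndim != 2:
        raise ValueError("window must be 2-D")
    offsets = [offset] if np.ndim(offset[0]) == 0 else list(offset)
    counts = np.zeros((levels, levels), dtype=float)
    rows, cols = q.shape
    for dr, dc in offsets:
        a = q[max(0, -dr) : rows - max(0, dr), max(0, -dc) : cols - max(0, dc)]
        b = q[max(0, dr) : rows + min(0, dr), max(0, dc) : cols + min(0, dc)]
        valid = (a >= 0) & (b >= 0)
        np.add.at(counts, (a[valid], b[valid]), 1.0)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise DomainError("no valid pixel pair at the requested offset(s)")
    return counts / total


def haralick_stats(P: np.ndarray) -> dict[str, float]:
    """The eight texture statistics of a normalized GLCM."""
    P = np.asarray(P, dtype=float)
    L = P.shape[0]
    if P.shape != (L, L) or abs(P.sum() - 1.0) > 1e-9 or (P < 0).any():
        raise ValueError("P must be a normalized co-occurrence matrix")
    i = np.arange(L, dtype=float)
    p_i = P.sum(axis=1)
    p_j = P.sum(axis=0)
    mu_i = float(i @ p_i)
    mu_j = float(i @ p_j)
    var_i = float(((i - mu_i) ** 2) @ p_i)
    var_j = float(((i - mu_j) ** 2) @ p_j)
    diff = i[:, None] - i[None, :]
    con = float((diff**2 * P).sum())
    dis = float((np.abs(diff) * P).sum())
    hom = float((P / (1.0 + diff**2)).sum())
    pos = P[P > 0]
    ent = float(-(pos * np.log(pos)).sum())
    sm = float((P**2).sum())
    if var_i > 0 and var_j > 0:
        cov = float(((i[:, None] - mu_i) * (i[None, :] - mu_j) * P).sum())
        cor = cov / np.sqrt(var_i * var_j)
    else:
        cor = 0.0
    return {
        "mean": mu_i, "var": var_i, "hom": hom, "con": con,
        "dis": dis, "ent": ent, "sm": sm, "cor": cor,
    }


def _window_pair_codes(q: np.ndarray, config: GLCMConfig) -> np.ndarray:
    """(n_windows, n_pairs) array of pair codes i*L + j per centered window.

    Windows are enumerated row-major over interior centers.  Requires a
    fully valid (no -1) quantized raster.
    """
    L = config.levels
    w = config.window
    rows, cols = q.shape
    blocks = []
    code = q.astype(np.int64)
    for dr, dc in config.offsets:
        a = code[max(0, -dr) : rows - max(0, dr), max(0, -dc) : cols - max(0, dc)]
        b = code[max(0, dr) : rows + min(0, dr), max(0, dc) : cols + min(0, dc)]
        pair = a * L + b
        # windows of the pair grid aligned so entry [cr-h, cc-h] collects
        # exactly the pairs wholly inside the window centered at (cr, cc)
        view = sliding_window_view(pair, (w - abs(dr), w - abs(dc)))
        blocks.append(view.reshape(view.shape[0] * view.shape[1], -1))
        if config.symmetric:
            swapped = b * L + a
            sview = sliding_window_view(swapped, (w - abs(dr), w - abs(dc)))
            blocks.append(sview.reshape(sview.shape[0] * sview.shape[1], -1))
    return np.concatenate(blocks, axis=1)


def texture_maps(
    band_raster: np.ndarray, config: GLCMConfig
) -> dict[str, np.ndarray]:
    """Windowed texture-statistic maps for one band.

    Returns one float raster per statistic, same shape as the input, with
    NaN at border pixels whose window is incomplete.  Interior values equal
    the statistics of the pooled, symmetrized, normalized window GLCM.
    """
    arr = np.asarray(band_raster, dtype=float)
    if arr.ndim != 2:
        raise ValueError("band raster must be 2-D")
    if not np.isfinite(arr).all():
        raise ValueError("texture_maps requires a fully finite raster")
    w = config.window
    if arr.shape[0] < w or arr.shape[1] < w:
        raise ValueError(
            f"raster {arr.shape} smaller than the {w}x{w} texture window"
        )
    q = quantize(arr, config.levels)
    L = config.levels
    h = w // 2

    codes = _window_pair_codes(q, config)
    m, n = codes.shape
    i = (codes // L).astype(np.float64)
    j = (codes % L).astype(np.float64)
    mean_i = i.mean(axis=1)
    mean_j = j.mean(axis=1)
    var_i = i.var(axis=1)
    var_j = j.var(axis=1)
    d = i - j
    con = (d * d).mean(axis=1)
    dis = np.abs(d).mean(axis=1)
    hom = (1.0 / (1.0 + d * d)).mean(axis=1)
    cov = (i * j).mean(axis=1) - mean_i * mean_j
    denom = np.sqrt(var_i * var_j)
    cor = np.divide(cov, denom, out=np.zeros(m), where=denom > 0)

    # entropy / second moment need the joint distribution: run-length encode
    # the sorted pair codes of each window
    S = np.sort(codes, axis=1)
    flat = S.ravel()
    is_new = np.empty(flat.shape, dtype=bool)
    is_new[0] = True
    is_new[1:] = flat[1:] != flat[:-1]
    is_new[::n] = True  # each window starts its own runs
    starts = np.flatnonzero(is_new)
    lengths = np.diff(np.append(starts, flat.size))
    p = lengths / n
    win = starts // n
    ent = np.bincount(win, weights=-(p * np.log(p)), minlength=m)
    sm = np.bincount(win, weights=p * p, minlength=m)

    interior = (arr.shape[0] - 2 * h, arr.shape[1] - 2 * h)
    out = {}
    values = {
        "mean": mean_i, "var": var_i, "hom": hom, "con": con,
        "dis": dis, "ent": ent, "sm": sm, "cor": cor,
    }
    for name in STAT_NAMES:
        full = np.full(arr.shape, np.nan)
        full[h : h + interior[0], h : h + interior[1]] = values[name].reshape(interior)
        out[name] = full
    return out


def texture_feature_names(config: GLCMConfig) -> list[str]:
    """The ``{stat}_{band}`` column names, stats fastest within each band."""
    return [f"{s}_{b}" for b in config.bands for s in STAT_NAMES]


def roi_texture_means(
    texture_maps_per_band: Mapping[int, Mapping[str, np.ndarray]],
    mask: np.ndarray,
) -> dict[str, float]:
    """Mean of each statistic map over the ROI mask, per band.

    Border (NaN) pixels are ignored; an ROI covering only border pixels
    raises :class:`EmptyROIError`.  Returns ``8 * n_bands`` named values.
    """
    if not mask.any():
        raise EmptyROIError("ROI mask selects no pixels")
    out: dict[str, float] = {}
    for band, maps in texture_maps_per_band.items():
        for stat in STAT_NAMES:
            vals = maps[stat][mask]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                raise EmptyROIError(
                    f"ROI covers only border pixels for stat {stat}_{band}"
                )
            out[f"{stat}_{band}"] = float(vals.mean())
    return out


def roi_texture_table(
    stack, rois: Mapping[str, object], config: GLCMConfig
) -> pd.DataFrame:
    """Per-plot texture features for one raster: maps once, then ROI means."""
    from .raster import roi_mask  # local import to avoid a cycle

    maps_by_band = {b: texture_maps(stack.band(b), config) for b in config.bands}
    cols = texture_feature_names(config)
    records = []
    for pid, roi in rois.items():
        mask = roi_mask(stack.shape, roi)
        if not mask.any():
            raise EmptyROIError(f"ROI for plot {pid} selects no pixels")
        records.append({"plot_id": pid, **roi_texture_means(maps_by_band, mask)})
    return pd.DataFrame.from_records(records, columns=["plot_id", *cols])
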