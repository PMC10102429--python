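"""The eight vegetation indices used for LAI screening.

Each index is an algebraic combination of the blue (475 nm), red (650 nm),
red-edge (705 nm) and NIR (842 nm) band reflectances.  The formulas are kept
exactly as used in the source field study ("study dialect"), even where a
variant differs from other forms circulating in the literature — notably
MTCI here uses the red band in its denominator, and OSAVI is the
(1 + 0.16) soil-adjusted form.
"""
from __future__ import annotations

from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, MissingBandError

_EPS = 0.0  # denominators must be exactly non-zero; no fudge factor


def _div(num, den, context: str):
    if np.ndim(den) == 0:
        if den == 0:
            raise DomainError(f"zero denominator in {context}")
        return num / den
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den == 0, np.nan, num / den)
    return out


def _ndvi(b):
    return _div(b[842] - b[650], b[842] + b[650], "NDVI")


def _ndre(b):
    return _div(b[842] - b[705], b[842] + b[705], "NDRE")


def _mtci(b):
    # study dialect: red band, not red edge, completes the denominator
    return _div(b[842] - b[705], b[705] + b[650], "MTCI")


def _dvi(b):
    return b[842] - b[650]


def _rvi(b):
    return _div(b[842], b[650], "RVI")


def _ci_red_edge(b):
    return _div(b[842], b[705], "CIrededge") - 1.0


def _evi(b):
    return 2.5 * _div(b[842] - b[650], b[842] + 6.0 * b[650] - 7.5 * b[475] + 1.0, "EVI")


def _osavi(b):
    return (1.0 + 0.16) * _div(b[842] - b[650], b[842] + b[650] + 0.16, "OSAVI")


#: Registry: index name -> (required wavelengths, formula).
VI_REGISTRY: dict[str, tuple[tuple[int, ...], Callable]] = {
    "NDVI": ((650, 842), _ndvi),
    "NDRE": ((705, 842), _ndre),
    "MTCI": ((650, 705, 842), _mtci),
    "DVI": ((650, 842), _dvi),
    "RVI": ((650, 842), _rvi),
    "CIrededge": ((705, 842), _ci_red_edge),
    "EVI": ((475, 650, 842), _evi),
    "OSAVI": ((650, 842), _osavi),
}

VI_NAMES: tuple[str, ...] = tuple(VI_REGISTRY)


def compute_vi(name: str, reflectance_by_band: Mapping[int, float]):
    """Evaluate one vegetation index from a {wavelength_nm: reflectance} map.

    Scalar inputs with a zero denominator raise :class:`DomainError`; array
    inputs return NaN at the offending rows (callers treat NaN as missing).
    """
    if name not in VI_REGISTRY:
        raise KeyError(f"unknown vegetation index {name!r}; known: {VI_NAMES}")
    required, fn = VI_REGISTRY[name]
    vals = {}
    for wl in required:
        if wl not in reflectance_by_band:
            raise MissingBandError(wl)
        vals[wl] = reflectance_by_band[wl]
        if np.ndim(vals[wl]) == 0 and not np.isfinite(vals[wl]):
            raise ValueError(f"non-finite reflectance for band {wl} in {name}")
    return fn(vals)


def vi_table(table: pd.DataFrame, on_error: str = "raise") -> pd.DataFrame:
    """Append the eight vegetation-index columns to a band-mean table.

    Requires columns ``b475``, ``b650``, ``b705``, ``b842``.  With
    ``on_error="raise"`` a zero denominator aborts, naming the offending row;
    with ``on_error="nan"`` the affected cells are left missing so that
    correlation screening can treat them as absent.
    """
    if on_error not in ("raise", "nan"):
        raise ValueError("on_error must be 'raise' or 'nan'")
    needed = {475: "b475", 650: "b650", 705: "b705", 842: "b842"}
    for wl, col in needed.items():
        if col not in table.columns:
            raise MissingBandError(wl)
    out = table.copy()
    bands = {wl: out[col].to_numpy(dtype=float) for wl, col in needed.items()}
    for name in VI_NAMES:
        values = compute_vi(name, bands)
        values = np.asarray(values, dtype=float)
        if on_error == "raise" and len(out) and not np.all(np.isfinite(values)):
            bad = np.flatnonzero(~np.isfinite(values))[0]
            ident = (
                out.iloc[bad]["plot_id"] if "plot_id" in out.columns else f"row {bad}"
            )
            raise DomainError(f"{name} undefined for {ident}")
        out[name] = values
    return out
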