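"""Correlation screening of candidate features against LAI.

Every band mean, vegetation index, texture feature and selected texture
index is correlated with the pooled LAI sample (all acquisition dates
together).  Significance uses the exact t-test for a Pearson coefficient,

    t = r * sqrt((n - 2) / (1 - r^2)),  df = n - 2,

flagged with the conventional raw-p star convention (* p < 0.05,
** p < 0.01; no multiple-testing correction, which callers should keep in
mind when reading long feature lists).  Vegetation indices pass screening
when |r| reaches the selection threshold (default 0.700).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DomainError, TexlaiError

DEFAULT_VI_THRESHOLD = 0.700


@dataclass(frozen=True)
class CorrelationReport:
    feature_name: str
    r: float
    n: int
    p_value: float
    stars: str


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation over complete pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise DomainError(f"need at least 3 complete pairs, got {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        raise DomainError("correlation undefined for a zero-variance input")
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))


def r_significance(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson r from n paired samples."""
    if n < 3:
        raise DomainError("significance needs n >= 3")
    if abs(r) >= 1.0:
        return 0.0  # exact linear relation
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def significance_stars(p_value: float) -> str:
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


def correlation_report(name: str, x, lai) -> CorrelationReport:
    x = np.asarray(x, dtype=float)
    y = np.asarray(lai, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    r = pearson_r(x[ok], y[ok])
    n = int(ok.sum())
    p = r_significance(r, n)
    return CorrelationReport(name, r, n, p, significance_stars(p))


def screen_features(
    feature_table: pd.DataFrame,
    band_cols: Sequence[str],
    vi_cols: Sequence[str],
    texture_cols: Sequence[str],
    ti_cols: Sequence[str],
    lai_col: str = "lai",
    vi_threshold: float = DEFAULT_VI_THRESHOLD,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Correlate every candidate feature with LAI and build model input sets.

    Returns (report table, feature sets).  The report covers, in order, the
    band means, vegetation indices, per-band texture features and selected
    texture indices — one row per feature, none silently dropped.  The
    ``VIs`` set keeps vegetation indices with |r| >= *vi_threshold*, ordered
    by descending |r| then name; ``TIs`` keeps the given texture indices;
    ``VIs+TIs`` is their concatenation.
    """
    if lai_col not in feature_table.columns:
        raise TexlaiError(f"feature table has no {lai_col!r} column")
    lai = feature_table[lai_col].to_numpy(dtype=float)
    groups = [
        ("band", band_cols),
        ("vegetation_index", vi_cols),
        ("texture", texture_cols),
        ("texture_index", ti_cols),
    ]
    rows = []
    for group, cols in groups:
        for c in cols:
            if c not in feature_table.columns:
                raise TexlaiError(f"screened feature {c!r} missing from table")
            rep = correlation_report(c, feature_table[c], lai)
            rows.append(
                {
                    "feature": c,
                    "group": group,
                    "r": rep.r,
                    "n": rep.n,
                    "p": rep.p_value,
                    "stars": rep.stars,
                }
            )
    report = pd.DataFrame(rows)

    vi_rep = report[report["group"] == "vegetation_index"].copy()
    vi_rep["abs_r"] = vi_rep["r"].abs()
    kept = vi_rep[vi_rep["abs_r"] >= vi_threshold]
    kept = kept.sort_values(["abs_r", "feature"], ascending=[False, True])
    selected_vis = list(kept["feature"])
    sets = {
        "VIs": selected_vis,
        "TIs": list(ti_cols),
        "VIs+TIs": selected_vis + list(ti_cols),
    }
    return report, sets
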