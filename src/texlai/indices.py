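"""Texture indices: pairwise combinations of texture features.

Single texture features are often weakly related to canopy LAI; combining
two of them sharpens the signal the same way band-ratio vegetation indices
do.  Three families are traversed over all ordered pairs (T1, T2) of the
texture features (cross-band pairs included):

    NDTI = (T1 - T2) / (T1 + T2)
    RTI  = T1 / T2
    DTI  = T1 - T2

Each pair's index column is correlated with LAI (Pearson, pairwise-complete)
and the best-|r| pair per family is selected for modeling.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, TexlaiError

INDEX_KINDS: tuple[str, ...] = ("NDTI", "RTI", "DTI")


@dataclass(frozen=True)
class TextureIndexDef:
    """One selected texture index: kind plus the ordered feature pair."""

    kind: str
    t1_name: str
    t2_name: str
    r: float | None = None  # correlation with LAI at selection time

    @property
    def name(self) -> str:
        return f"{self.kind}({self.t1_name},{self.t2_name})"

    def compute(self, table: pd.DataFrame) -> np.ndarray:
        return texture_index(
            self.kind,
            table[self.t1_name].to_numpy(dtype=float),
            table[self.t2_name].to_numpy(dtype=float),
        )


def texture_index(kind: str, t1, t2):
    """Evaluate one texture index.

    Scalars with an undefined value (zero denominator) raise
    :class:`DomainError`; arrays yield NaN there, treated as missing
    downstream.
    """
    if kind not in INDEX_KINDS:
        raise KeyError(f"unknown texture index kind {kind!r}")
    scalar = np.ndim(t1) == 0 and np.ndim(t2) == 0
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if kind == "DTI":
        out = t1 - t2
    else:
        den = (t1 + t2) if kind == "NDTI" else t2
        if scalar and den == 0:
            raise DomainError(f"zero denominator in {kind}")
        with np.errstate(divide="ignore", invalid="ignore"):
            num = (t1 - t2) if kind == "NDTI" else t1
            out = np.where(den == 0, np.nan, num / den)
    return float(out) if scalar else out


def traverse_pairs(
    feature_table: pd.DataFrame,
    kinds: Sequence[str] = INDEX_KINDS,
    feature_names: Sequence[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Index values over all ordered feature pairs, one table per kind.

    Each returned frame has the sample index of *feature_table* and a
    two-level (t1, t2) column MultiIndex covering every ordered pair,
    diagonal included (degenerate by construction: DTI 0, RTI 1, NDTI 0).
    Undefined entries are NaN.
    """
    if feature_names is None:
        feature_names = list(feature_table.columns)
    missing = [c for c in feature_names if c not in feature_table.columns]
    if missing:
        raise TexlaiError(f"texture columns missing from table: {missing}")
    T = feature_table[list(feature_names)].to_numpy(dtype=float)
    n, m = T.shape
    A = T[:, :, None]  # t1 varies along axis 1
    B = T[:, None, :]  # t2 along axis 2
    columns = pd.MultiIndex.from_product(
        [feature_names, feature_names], names=["t1", "t2"]
    )
    out = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for kind in kinds:
            if kind == "NDTI":
                den = A + B
                vals = np.where(den == 0, np.nan, (A - B) / den)
            elif kind == "RTI":
                vals = np.where(B == 0, np.nan, A / B)
            elif kind == "DTI":
                vals = A - B
            else:
                raise KeyError(f"unknown texture index kind {kind!r}")
            out[kind] = pd.DataFrame(
                vals.reshape(n, m * m), index=feature_table.index, columns=columns
            )
    return out


def _pairwise_pearson_with(X: np.ndarray, y: np.ndarray, min_n: int = 3) -> np.ndarray:
    """Pearson r of each column of X with y, over pairwise-complete rows."""
    valid = np.isfinite(X) & np.isfinite(y)[:, None]
    Xv = np.where(valid, np.nan_to_num(X), 0.0)
    Yv = np.where(valid, y[:, None], 0.0)
    n = valid.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        sx = Xv.sum(axis=0)
        sy = Yv.sum(axis=0)
        sxx = (Xv * Xv).sum(axis=0)
        syy = (Yv * Yv).sum(axis=0)
        sxy = (Xv * Yv).sum(axis=0)
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r = cov / np.sqrt(vx * vy)
    r[(n < min_n) | ~(np.sqrt(np.abs(vx * vy)) > 0)] = np.nan
    # guard tiny negative variances from cancellation
    r[~np.isfinite(r)] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)


def index_lai_correlation(
    index_tables: Mapping[str, pd.DataFrame], lai: Sequence[float]
) -> dict[str, pd.DataFrame]:
    """Per-kind matrices of Pearson r between each index column and LAI.

    Rows are t1, columns t2.  Cells with fewer than 3 complete samples or a
    constant index column are NaN (missing), never an error.
    """
    y = np.asarray(lai, dtype=float)
    out = {}
    for kind, tab in index_tables.items():
        if len(tab) != len(y):
            raise TexlaiError(
                f"LAI length {len(y)} does not match index table {len(tab)}"
            )
        r = _pairwise_pearson_with(tab.to_numpy(dtype=float), y)
        series = pd.Series(r, index=tab.columns)
        order = tab.columns.get_level_values("t1").unique()
        out[kind] = series.unstack(level="t2").reindex(index=order, columns=order)
    return out


def select_best_indices(
    correlation_matrices: Mapping[str, pd.DataFrame], k_per_kind: int = 1
) -> list[TextureIndexDef]:
    """Per kind, the off-diagonal pair(s) maximizing |r| with LAI.

    Ties break lexicographically on (t1, t2).  Diagonal (t1 == t2) cells are
    degenerate and never selected.
    """
    selected: list[TextureIndexDef] = []
    for kind, mat in correlation_matrices.items():
        if mat.size == 0:
            raise TexlaiError(f"empty correlation matrix for {kind}")
        stacked = mat.stack()  # (t1, t2) -> r, NaNs dropped
        stacked = stacked[
            stacked.index.get_level_values(0) != stacked.index.get_level_values(1)
        ]
        if stacked.empty:
            raise TexlaiError(f"no defined off-diagonal correlation for {kind}")
        ranked = pd.DataFrame(
            {
                "t1": stacked.index.get_level_values(0),
                "t2": stacked.index.get_level_values(1),
                "r": stacked.to_numpy(dtype=float),
            }
        )
        ranked["abs_r"] = ranked["r"].abs()
        ranked = ranked.sort_values(
            ["abs_r", "t1", "t2"], ascending=[False, True, True]
        )
        for _, row in ranked.head(k_per_kind).iterrows():
            selected.append(
                TextureIndexDef(kind, row["t1"], row["t2"], r=float(row["r"]))
            )
    return selected


def append_index_columns(
    table: pd.DataFrame, defs: Sequence[TextureIndexDef]
) -> pd.DataFrame:
    """Append one named column per selected texture index."""
    out = table.copy()
    for d in defs:
        out[d.name] = d.compute(table)
    return out
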