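"""Summary arithmetic over cross-validation results tables.

Given the tidy results table (family x input set x Cal/Val with R2, RMSE,
RPD), this module computes across-family means per input set and the
percent changes between input sets — the numbers used to judge whether
fusing spectral and textural features buys accuracy.

A reference results table from the original maize UAV field experiment
(140 varieties, five growth stages, 700 plot samples) ships with the
package so the same summary arithmetic can be applied to published
benchmark numbers.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import TexlaiError
from .modeling import FAMILIES

_METRICS = ("R2", "RMSE", "RPD")
_SPLITS = ("Cal", "Val")


@dataclass(frozen=True)
class PercentChange:
    """Signed percent change of *value* relative to *reference*.

    ``magnitude`` is always positive; ``direction`` is ``"increase"``,
    ``"decrease"`` or ``"unchanged"``, matching how such shifts are usually
    quoted in prose ("RMSE increased by 66.827%").
    """

    signed: float
    magnitude: float
    direction: str


def percent_change(reference: float, value: float) -> PercentChange:
    if reference == 0:
        raise TexlaiError("percent change undefined for a zero reference")
    signed = 100.0 * (value - reference) / reference
    if signed > 0:
        return PercentChange(signed, signed, "increase")
    if signed < 0:
        return PercentChange(signed, -signed, "decrease")
    return PercentChange(0.0, 0.0, "unchanged")


def _require_complete(results: pd.DataFrame) -> None:
    have = set(zip(results["family"], results["input_set"], results["split"]))
    sets = results["input_set"].unique()
    missing = [
        (f, s, sp)
        for f in FAMILIES
        for s in sets
        for sp in _SPLITS
        if (f, s, sp) not in have
    ]
    if missing:
        raise TexlaiError(f"results table incomplete; missing cells: {missing}")


def summarize_input_sets(
    results: pd.DataFrame, fused: str = "VIs+TIs"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Across-family metric means per input set, plus fusion percent changes.

    Returns ``(means, changes)``: *means* has one row per (input_set, split)
    with the across-family mean of each metric; *changes* compares the
    *fused* set against every other input set, one row per
    (reference set, split, metric) with the signed percent change and its
    direction label.
    """
    _require_complete(results)
    means = (
        results.groupby(["input_set", "split"], sort=False)[list(_METRICS)]
        .mean()
        .reset_index()
    )
    if fused not in set(means["input_set"]):
        raise TexlaiError(f"fused input set {fused!r} absent from results")
    rows = []
    for ref_set in means["input_set"].unique():
        if ref_set == fused:
            continue
        for split in _SPLITS:
            for metric in _METRICS:
                ref = float(
                    means.query("input_set == @ref_set and split == @split")[
                        metric
                    ].iloc[0]
                )
                val = float(
                    means.query("input_set == @fused and split == @split")[
                        metric
                    ].iloc[0]
                )
                ch = percent_change(ref, val)
                rows.append(
                    {
                        "reference_set": ref_set,
                        "split": split,
                        "metric": metric,
                        "reference": ref,
                        "fused": val,
                        "percent_change": ch.signed,
                        "magnitude": ch.magnitude,
                        "direction": ch.direction,
                    }
                )
    return means, pd.DataFrame(rows)


def family_split_changes(results: pd.DataFrame, family: str,
                         input_set: str = "VIs+TIs") -> pd.DataFrame:
    """Calibration-to-validation percent change of each metric for one model."""
    rows = []
    for metric in _METRICS:
        sub = results[
            (results["family"] == family) & (results["input_set"] == input_set)
        ]
        try:
            cal = float(sub[sub["split"] == "Cal"][metric].iloc[0])
            val = float(sub[sub["split"] == "Val"][metric].iloc[0])
        except IndexError:
            raise TexlaiError(f"missing Cal/Val cells for {family}/{input_set}")
        ch = percent_change(cal, val)
        rows.append(
            {
                "metric": metric,
                "Cal": cal,
                "Val": val,
                "percent_change": ch.signed,
                "magnitude": ch.magnitude,
                "direction": ch.direction,
            }
        )
    return pd.DataFrame(rows)


def load_field_benchmark() -> pd.DataFrame:
    """Published cross-validation results of the original field experiment."""
    with resources.files("texlai.data").joinpath("field_benchmark.csv").open() as fh:
        return pd.read_csv(fh)
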