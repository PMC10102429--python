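"""End-to-end orchestration: scene -> features -> screening -> models -> summary.

The pipeline runs either on a synthetic campaign (generated in place from a
``synthetic`` config block) or on user-supplied rasters, ROIs and an LAI
table.  Every stage writes plain CSV/JSON artifacts into the output
directory and the run closes with a manifest listing each file with a
content hash, so a run is auditable and byte-reproducible for a fixed seed.
"""
from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bands import REDEDGE_MX_DUAL
from .errors import TexlaiError
from .indices import (INDEX_KINDS, append_index_columns, index_lai_correlation,
                      select_best_indices, traverse_pairs)
from .modeling import FAMILIES, run_experiment
from .raster import band_mean_table, load_rois, read_stack
from .report import summarize_input_sets
from .screening import DEFAULT_VI_THRESHOLD, screen_features
from .spectral import VI_NAMES, vi_table
from .synthetic import CanopyParams, generate_dataset
from .texture import GLCMConfig, roi_texture_table, texture_feature_names

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated run configuration.

    Exactly one of ``synthetic`` (CanopyParams fields) or ``inputs``
    (``rasters``: list of multiband TIFF paths named ``*_<date>.tif``,
    ``rois``: GeoJSON/CSV path, ``lai``: CSV with plot_id,date,lai) must be
    given.  ``seed`` is mandatory.
    """

    seed: int
    output_dir: Path
    synthetic: dict | None = None
    inputs: dict | None = None
    texture: dict = field(default_factory=dict)
    screening: dict = field(default_factory=dict)
    models: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise TexlaiError(
                "config must set exactly one of 'synthetic' and 'inputs'"
            )
        self.output_dir = Path(self.output_dir)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "seed" not in raw:
            raise TexlaiError("config must declare a seed")
        return cls(
            seed=int(raw["seed"]),
            output_dir=Path(raw.get("output_dir", "texlai_out")),
            synthetic=raw.get("synthetic"),
            inputs=raw.get("inputs"),
            texture=raw.get("texture", {}),
            screening=raw.get("screening", {}),
            models=raw.get("models", {}),
        )

    def canopy_params(self) -> CanopyParams:
        block = dict(self.synthetic or {})
        block.setdefault("seed", self.seed)
        if "plot_size" in block:
            block["plot_size"] = tuple(block["plot_size"])
        if "lai_range" in block:
            block["lai_range"] = tuple(block["lai_range"])
        return CanopyParams(**block)

    def glcm_config(self) -> GLCMConfig:
        block = dict(self.texture)
        if "offsets" in block:
            block["offsets"] = tuple(tuple(o) for o in block["offsets"])
        if "bands" in block:
            block["bands"] = tuple(block["bands"])
        return GLCMConfig(**block)


_DATE_RE = re.compile(r"(\d{4}-\d{2}-\d{2})")


def _date_from_name(path: Path) -> str:
    m = _DATE_RE.search(path.stem)
    if not m:
        raise TexlaiError(f"cannot parse an ISO date from raster name {path.name}")
    return m.group(1)


def build_feature_table(
    rasters: Mapping[str, Path],
    rois: Mapping[str, object],
    lai: pd.DataFrame,
    glcm_config: GLCMConfig,
    vi_on_error: str = "nan",
) -> pd.DataFrame:
    """Assemble the per-plot-per-date feature table.

    Columns: plot_id, date, lai, the per-band means (``b444``..``b842``),
    the eight vegetation indices, and the per-band texture features.
    """
    required = {"plot_id", "date", "lai"}
    if not required <= set(lai.columns):
        raise TexlaiError(f"LAI table must have columns {sorted(required)}")
    frames = []
    for date, src in sorted(rasters.items()):
        stack = src if hasattr(src, "pixels") else read_stack(src)
        bands = band_mean_table(stack, rois)
        tex = roi_texture_table(stack, rois, glcm_config)
        merged = bands.merge(tex, on="plot_id")
        merged.insert(1, "date", date)
        frames.append(merged)
        log.info("extracted %d plots for %s", len(merged), date)
    table = pd.concat(frames, ignore_index=True)
    lai = lai.copy()
    lai["plot_id"] = lai["plot_id"].astype(str)
    lai["date"] = lai["date"].astype(str)
    table = table.merge(lai[["plot_id", "date", "lai"]], on=["plot_id", "date"],
                        how="left")
    if table["lai"].isna().any():
        bad = table[table["lai"].isna()][["plot_id", "date"]].iloc[0]
        raise TexlaiError(
            f"no LAI ground truth for plot {bad.plot_id} on {bad.date}"
        )
    return vi_table(table, on_error=vi_on_error)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write all artifacts under ``output_dir``.

    Returns a dict with the in-memory feature table, screening report,
    experiment results and the manifest.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s: %(message)s"))
    root = logging.getLogger("texlai")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    written: list[Path] = []
    try:
        return _run_stages(config, out, written)
    except Exception as exc:
        raise TexlaiError(f"pipeline aborted: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_stages(config: PipelineConfig, out: Path, written: list[Path]) -> dict:
    glcm_config = config.glcm_config()

    # -- stage 1: inputs -----------------------------------------------------
    if config.synthetic is not None:
        params = config.canopy_params()
        log.info("simulating %d plots x %d dates", params.n_plots, params.n_dates)
        sim = generate_dataset(params, out / "synthetic")
        rasters = sim["rasters"]
        rois = load_rois(sim["rois"])
        lai = pd.read_csv(sim["lai_table"])
    else:
        paths = [Path(p) for p in config.inputs["rasters"]]
        for p in paths:
            if not p.exists():
                raise FileNotFoundError(f"raster not found: {p}")
        rasters = {_date_from_name(p): p for p in paths}
        rois = load_rois(config.inputs["rois"])
        lai_path = Path(config.inputs["lai"])
        if not lai_path.exists():
            raise FileNotFoundError(f"LAI table not found: {lai_path}")
        lai = pd.read_csv(lai_path)

    # -- stage 2: feature extraction ----------------------------------------
    table = build_feature_table(rasters, rois, lai, glcm_config)
    log.info("feature table: %d rows x %d columns", *table.shape)

    # -- stage 3: texture indices -------------------------------------------
    tex_cols = texture_feature_names(glcm_config)
    pair_tables = traverse_pairs(table, INDEX_KINDS, tex_cols)
    corr = index_lai_correlation(pair_tables, table["lai"])
    for kind, mat in corr.items():
        p = out / f"texture_index_correlations_{kind}.csv"
        mat.to_csv(p)
        written.append(p)
    defs = select_best_indices(corr, k_per_kind=1)
    sel = pd.DataFrame(
        [{"kind": d.kind, "t1": d.t1_name, "t2": d.t2_name, "r": d.r,
          "name": d.name} for d in defs]
    )
    sel_path = out / "selected_indices.csv"
    sel.to_csv(sel_path, index=False)
    written.append(sel_path)
    table = append_index_columns(table, defs)
    ti_cols = [d.name for d in defs]

    feat_path = out / "features.csv"
    table.to_csv(feat_path, index=False)
    written.append(feat_path)

    # -- stage 4: screening ---------------------------------------------------
    band_cols = [b.column for b in REDEDGE_MX_DUAL if b.column in table.columns]
    threshold = config.screening.get("vi_threshold", DEFAULT_VI_THRESHOLD)
    report, sets = screen_features(
        table, band_cols, list(VI_NAMES), tex_cols, ti_cols,
        vi_threshold=threshold,
    )
    rep_path = out / "correlations.csv"
    report.to_csv(rep_path, index=False)
    written.append(rep_path)
    sets_path = out / "feature_sets.json"
    sets_path.write_text(json.dumps(sets, indent=1))
    written.append(sets_path)
    log.info("screening kept %d vegetation indices", len(sets["VIs"]))

    # -- stage 5: modeling ----------------------------------------------------
    families = config.models.get("families", list(FAMILIES))
    experiment = run_experiment(
        table,
        sets,
        seed=config.seed,
        families=families,
        hyperparameters=config.models.get("hyperparameters"),
    )
    res_path = out / "results_table.csv"
    experiment["results"].to_csv(res_path, index=False)
    written.append(res_path)
    pred_path = out / "predictions.csv"
    experiment["predictions"].to_csv(pred_path, index=False)
    written.append(pred_path)
    folds_path = out / "folds.csv"
    pd.DataFrame({"fold": experiment["folds"]}).to_csv(folds_path, index=False)
    written.append(folds_path)

    # -- stage 6: summary -----------------------------------------------------
    means, changes = summarize_input_sets(experiment["results"])
    means_path = out / "summary_means.csv"
    means.to_csv(means_path, index=False)
    written.append(means_path)
    changes_path = out / "summary_changes.csv"
    changes.to_csv(changes_path, index=False)
    written.append(changes_path)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_samples": int(len(table)),
        "best_model": list(experiment["best"]),
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in written},
    }
    man_path = out / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=1))
    log.info("wrote %d artifacts to %s", len(written) + 1, out)
    return {
        "features": table,
        "screening": report,
        "feature_sets": sets,
        "selected_indices": defs,
        "experiment": experiment,
        "summary": (means, changes),
        "manifest": manifest,
    }
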