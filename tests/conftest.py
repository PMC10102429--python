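"""Shared fixtures and independent oracles.

The GLCM oracle here deliberately re-derives co-occurrence statistics by
explicit pair enumeration (nested Python loops, dictionary counting) so it
shares no code path with the vectorized implementation it checks.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from texlai.pipeline import PipelineConfig, run_pipeline
from texlai.synthetic import CanopyParams

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


# ---------------------------------------------------------------------------
# Brute-force GLCM oracle

def brute_glcm_counts(window, offsets, levels, symmetric):
    """Pair counts by explicit enumeration over every pixel and offset."""
    counts = {}
    rows, cols = window.shape
    for dr, dc in offsets:
        for r in range(rows):
            for c in range(cols):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols:
                    a, b = int(window[r, c]), int(window[r2, c2])
                    if a >= 0 and b >= 0:
                        counts[(a, b)] = counts.get((a, b), 0) + 1
                        if symmetric:
                            counts[(b, a)] = counts.get((b, a), 0) + 1
    return counts


def brute_glcm(window, offsets, levels, symmetric=True):
    counts = brute_glcm_counts(window, offsets, levels, symmetric)
    total = sum(counts.values())
    P = np.zeros((levels, levels))
    for (a, b), k in counts.items():
        P[a, b] = k / total
    return P


def brute_haralick(P):
    """Haralick statistics straight from the defining sums."""
    L = P.shape[0]
    mu_i = sum(i * P[i, j] for i in range(L) for j in range(L))
    mu_j = sum(j * P[i, j] for i in range(L) for j in range(L))
    var_i = sum((i - mu_i) ** 2 * P[i, j] for i in range(L) for j in range(L))
    var_j = sum((j - mu_j) ** 2 * P[i, j] for i in range(L) for j in range(L))
    out = {
        "mean": mu_i,
        "var": var_i,
        "hom": sum(P[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L)),
        "con": sum((i - j) ** 2 * P[i, j] for i in range(L) for j in range(L)),
        "dis": sum(abs(i - j) * P[i, j] for i in range(L) for j in range(L)),
        "ent": -sum(
            P[i, j] * math.log(P[i, j])
            for i in range(L)
            for j in range(L)
            if P[i, j] > 0
        ),
        "sm": sum(P[i, j] ** 2 for i in range(L) for j in range(L)),
    }
    if var_i > 0 and var_j > 0:
        cov = sum(
            (i - mu_i) * (j - mu_j) * P[i, j] for i in range(L) for j in range(L)
        )
        out["cor"] = cov / math.sqrt(var_i * var_j)
    else:
        out["cor"] = 0.0
    return out


# ---------------------------------------------------------------------------
# Campaign fixtures

@pytest.fixture(scope="session")
def small_params():
    """A reduced campaign for fast structural tests."""
    return CanopyParams(n_plots=12, n_dates=3, plot_size=(32, 32), seed=123)


@pytest.fixture(scope="session")
def small_run(small_params, tmp_path_factory):
    """Full pipeline output on the reduced campaign (shared, read-only)."""
    out = tmp_path_factory.mktemp("small_run")
    cfg = PipelineConfig(
        seed=123,
        output_dir=out,
        synthetic={
            "n_plots": small_params.n_plots,
            "n_dates": small_params.n_dates,
            "plot_size": list(small_params.plot_size),
        },
    )
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def campaign(tmp_path_factory):
    """The default-scale campaign: 140 plots x 5 dates at 64x64 px.

    Generated once per session; provides the feature table, screening
    output and texture-index selection used by the study-scale tests.
    """
    import time

    from texlai.bands import REDEDGE_MX_DUAL
    from texlai.indices import (INDEX_KINDS, append_index_columns,
                                index_lai_correlation, select_best_indices,
                                traverse_pairs)
    from texlai.pipeline import build_feature_table
    from texlai.raster import load_rois
    from texlai.screening import screen_features
    from texlai.spectral import VI_NAMES
    from texlai.synthetic import generate_dataset
    from texlai.texture import GLCMConfig, texture_feature_names

    out = tmp_path_factory.mktemp("campaign")
    params = CanopyParams(seed=2021)
    t0 = time.time()
    sim = generate_dataset(params, out)
    rois = load_rois(sim["rois"])
    lai = pd.read_csv(sim["lai_table"])
    glcm_config = GLCMConfig()
    table = build_feature_table(sim["rasters"], rois, lai, glcm_config)
    extraction_seconds = time.time() - t0

    tex_cols = texture_feature_names(glcm_config)
    pair_tables = traverse_pairs(table, INDEX_KINDS, tex_cols)
    corr = index_lai_correlation(pair_tables, table["lai"])
    defs = select_best_indices(corr, k_per_kind=1)
    table = append_index_columns(table, defs)
    band_cols = [b.column for b in REDEDGE_MX_DUAL]
    report, sets = screen_features(
        table, band_cols, list(VI_NAMES), tex_cols, [d.name for d in defs]
    )
    return {
        "params": params,
        "features": table,
        "texture_columns": tex_cols,
        "correlations": corr,
        "selected": defs,
        "report": report,
        "sets": sets,
        "extraction_seconds": extraction_seconds,
    }
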