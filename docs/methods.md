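# Methods

## The estimation problem

Leaf area index (LAI) — one-sided green leaf area per unit ground area —
is the regression response. Predictors are features extracted from
multiband reflectance imagery of small field plots: per-band ROI-mean
reflectances, eight vegetation indices (VIs), twenty-four gray-level
co-occurrence (GLCM) texture features, and texture indices (TIs) formed
from pairs of texture features. Four regression families are compared on
three input sets (VIs, TIs, VIs+TIs) under ten-fold cross-validation.

## Synthetic campaign model

The generator emulates a variety-trial campaign: `n_plots` plots imaged on
`n_dates` dates (defaults 140 × 5, giving 700 samples, the size of the
emulated study).

**Ground truth.** Per-plot LAI combines a persistent uniform "vigour"
factor (0.55–1.0, standing in for variety differences), a rise-and-fall
phenology profile sin(πd/(D+1)) across dates (canopy development through
tasseling to ripening), and 6 % multiplicative Gaussian jitter, scaled into
`lai_range` (default 0.5–5.5 m²/m², a realistic span from canopy closure
onward) and clipped strictly inside it.

**Reflectance.** Expected plot reflectance follows two-endmember
Beer–Lambert mixing, R_b = soil_b·e^(−k_b·LAI) + leaf_b·(1−e^(−k_b·LAI)).
Default endmember spectra are piecewise-linear plausible soil (brightening
0.10→0.28 across 444–842 nm) and leaf (green bump, dark red, red-edge rise
between 717 and 740 nm, bright NIR) curves; extinction k is 0.8 in the
visible, 0.7 at the red edges, 0.6 in the NIR, so visible bands darken and
the NIR brightens with LAI — reproducing the sign structure real campaigns
show (negative band–LAI correlation through 717 nm, positive at 740–842
nm).

**Texture.** A Gaussian random field smoothed with σ = `gap_scale`
(default 4 px, a plausible gap patch size at plot resolution) is
thresholded so that exactly round(g·n) pixels are canopy gaps, where
g = e^(−k_ref·LAI) uses the NIR extinction as reference. Gap pixels show
soil; canopy pixels take the per-band value that makes the noise-free image
mean equal the mixing curve exactly. i.i.d. Gaussian sensor noise
(sd 0.005 reflectance) is added and pixels clipped to [0, 1].

**What it does not emulate.** No radiative transfer, BRDF, illumination
drift between flights, row structure, variety-specific spectra, or LAI
measurement error. One consequence matters for interpretation: ROI
averaging (≈3600 px) reduces the sensor-noise standard error of a plot
mean to ~8·10⁻⁵, and the exact-mean rendering removes gap-sampling
variance, so plot-level features are nearly deterministic functions of
LAI. Correlations and model R² on synthetic data are therefore much higher
than on real UAV data, and the synthetic campaign probes the pipeline's
correctness, not field-level accuracy. In particular, because the
unsaturated, nearly noise-free VIs are already a sufficient statistic for
LAI here, appending TIs cannot systematically improve validation R² the
way it does on real imagery, where saturation and measurement noise leave
texture with complementary information; the fusion-gain property is
asserted at study scale in the acceptance suite and is expected to sit at
the margin on this generator.

## Raster conventions

Pixels are 0-based row-major; a pixel covers the half-open square
[col, col+1) × [row, row+1) with its center at (+0.5, +0.5); ROI
membership is center-in-polygon. Bands are identified by center wavelength
from a registry embedded in the TIFF metadata, never by position.
Radiometric calibration is the standard single-panel zero-intercept gain
(reflectance = DN · panel_reflectance/panel_DN per band); multi-panel
affine fits are out of scope.

## Vegetation indices

Implemented exactly as used in the emulated study, including its MTCI
variant (NIR−RE)/(RE+R) and the (1+0.16) OSAVI form ("study dialect").
Zero denominators raise a domain error on scalars and propagate NaN in
table mode, where screening treats the row as missing — silent infinities
would corrupt correlations.

## GLCM texture

* Quantization: linear min–max over the full raster to 64 levels (per-window
  scaling would destroy cross-plot comparability of `mean`/`var`).
* Window 3×3 around each interior pixel; border pixels are NaN.
* Offsets (0,1), (1,1), (1,0), (1,−1): counts from all offsets are pooled
  into one matrix before symmetrization and normalization. Pooling weights
  offsets by their pair counts (6 horizontal/vertical vs 4 diagonal pairs
  in a 3×3 window); this matches the accumulate-then-normalize convention
  of common GLCM implementations and is exactly what the brute-force test
  oracle enumerates.
* Statistics: mean and var are reference-marginal moments; ent uses the
  natural log (a fixed base is needed for test vectors; base only
  rescales); cor is defined as 0 when a marginal variance vanishes so flat
  plots do not propagate NaN.
* The windowed implementation vectorizes all eight statistics as pair-code
  means plus a run-length encoding of sorted window pair codes (for ent and
  sm); it is verified cell-for-cell against explicit pair enumeration and
  against `skimage.feature.graycomatrix` on whole rasters.

The window size, level count and offsets are declared defaults (ENVI-style
occurrence settings), all config-overridable — the emulated study did not
state its texture-tool settings.

## Texture indices and screening

All 24² = 576 ordered pairs are traversed per index family: NDTI/DTI signs
and RTI reciprocals depend on pair order, and reported indices mix bands
(e.g. a cross-band NDTI), so the ordered, cross-band superset is the safe
search space. Correlations with LAI are pairwise-complete Pearson (isolated
domain errors must not delete a whole feature), cells with fewer than 3
complete samples or zero variance are missing, and per-family argmax-|r|
selection breaks ties lexicographically for determinism.

Feature screening reports raw two-sided p-values from the exact t-test with
the conventional star flags and applies no multiple-testing correction
(matching the raw-star convention of field studies; the report carries the
caveat). The VI selection threshold |r| ≥ 0.700 is configurable. All dates
are pooled into one sample, matching a single-campaign cross-validation
design.

## Modeling

* Folds: balanced random 10-fold split (630/70 at n = 700); one shared
  split per experiment so families are compared on identical partitions.
* SVM: RBF kernel, C = 1.00, γ = 3.03, features z-scored with training-fold
  statistics only.
* RF: 200 trees; mtry tuned per training fold by inner 5-fold CV over
  {1..p} maximizing validation R². The grid is ranked with 50-tree forests
  and the winner refit with 200 — mtry rankings stabilize quickly in tree
  count, and the full-size grid would dominate total runtime for no change
  in the selection rule.
* BPNN: one hidden layer of 10 units (the common reading of a "10 hidden
  layers, 1 output layer" description; a literal multi-layer variant is a
  config switch), Adam, learning rate 0.01, up to 2000 epochs, standardized
  features. A fold is flagged and excluded only if fitting fails or
  predictions are non-finite.
* PLSR: latent-variable count chosen per training fold by inner 5-fold CV
  over 1..min(p, 8) minimizing RMSE; variables scaled inside the model.
* Metrics: calibration metrics from in-fold training predictions,
  validation from held-out predictions; reported values are across-fold
  means. RPD uses the population-sd convention (divisor n), which makes the
  mean-predictor identity RPD = 1 exact; a perfect fit reports RPD = +inf.
* Leakage: scaling, mtry and latent-count selection all happen inside the
  training fold; the permuted-response acceptance test checks that
  validation R² then stays near zero for every family. Under permutation,
  kernel/linear families sit within a few hundredths of zero, while the
  random forest sits mildly negative (≈ −0.2): fully grown
  bootstrap-correlated trees give null predictions with variance around
  0.2·var(y), and R² ≈ −var(ŷ)/var(y) for predictions independent of the
  response. A negative value is the signature of *no* leakage — leaked
  information would push validation R² positive.

## Summary arithmetic

Across-family metric means per input set and percent changes
100·(value − reference)/reference, with positive-magnitude direction labels
("increase"/"decrease") as such shifts are quoted in prose. The same code
path is applied to the shipped benchmark results table of the original
field experiment; its fused-set means and the RF calibration-to-validation
shifts reproduce the published summary figures exactly, which pins the
arithmetic conventions.

## Problem sizes and determinism

Unit tests run on reduced campaigns (e.g. 12 plots × 3 dates at 32² px);
study-scale tests and the acceptance script use the full default campaign
(140 × 5 at 64² px, ~100 s to generate and extract on one core). The
noise-free recovery check keeps the 700-sample campaign but renders 32² px
plots, since its subject is the models, not the imagery. Every
stochastic component takes an explicit seed (NumPy `SeedSequence`-derived
child seeds per plot/date/model), and a fixed seed reproduces outputs
byte-identically.

## Known limitations

* Texture maps require fully finite rasters; masked/NoData imagery must be
  filled or cropped first.
* The synthetic campaign's near-noise-free plot means (above) make
  absolute metric levels incomparable to field results by design.
* Single-panel calibration ignores irradiance drift within a flight.
* No feature-importance or stage-stratified analysis; dates are pooled.
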