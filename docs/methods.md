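# Methods

This note documents the models, parameter choices and numerical
conventions behind `peatstack`, and what the synthetic-scene tests do
and do not demonstrate about real imagery.

## Compositing

**Cloud score.** The score of a pixel is the mean of five per-band
linear ramps. Each ramp rescales one band between a *clear* anchor
(score 0) and a *cloudy* anchor (score 1) and clips to [0, 1], so the
score is monotone non-decreasing in every input band. Default anchors
(reflectance units):

| band | clear | cloudy | rationale |
|---|---|---|---|
| Blue | 0.10 | 0.30 | most land/water surfaces are dark in blue; cloud is bright |
| Aerosol proxy | 0.10 | 0.30 | coastal-aerosol analogue, responds to haze |
| NIR | 0.25 | 0.80 | vegetation is bright but cloud brighter still |
| SWIR1 | 0.10 | 0.40 | separates cloud from bright bare soil |
| Cirrus proxy | 0.01 | 0.10 | thin cirrus detection |

Pixels with score ≥ 0.5 (default threshold) are invalidated; band
values are never altered by masking.

**Percentile-range composite.** Per pixel and band, the composite is
the mean of valid observations v with P₄₀ ≤ v ≤ P₆₀, where percentiles
use linear interpolation between order statistics. Conventions the
implementation pins down (and the brute-force test oracles freeze):

* the statistic is per-pixel-per-band, the only reading that yields a
  composite image;
* if the closed percentile interval captures no observation (possible
  with few observations), the single observation nearest the interval
  midpoint is used, ties going to the smaller value;
* pixels with fewer valid observations than `min_valid` (default 1)
  become nodata;
* with the (0, 100) range the composite equals the temporal mean, and
  it is invariant to the temporal order of the series.

Radar series are composited by the same operator without cloud
masking; inputs are assumed radiometrically calibrated upstream.

**Resampling** is nearest-neighbour on pixel centres, output grid
aligned to the source origin, single CRS assumed (a mismatch is an
error, never a silent reprojection). Categorical rasters therefore
never acquire new categories.

## Features

The 36 candidate layers and the six combinations (S2 10, S2+ 21, S1 2,
S1+ 12, S2+S1+ 33, S2+S1+DEM 36) are fixed lists; extraction outputs
physical values and standardisation happens later, on training pixels
only.

* **Vegetation indices**: six normalised differences (NDVI, NDWI,
  LSWI, NBR, NBR2, GNDVI), EVI, ARVI, MSAVI2 and the red-edge position
  S2REP = 705 + 35·((ρ_RE3 + ρ_Red)/2 − ρ_RE1)/(ρ_RE2 − ρ_RE1) (nm).
  Zero denominators give nodata.
* **Windowed standard deviation**: 5×5 population standard deviation,
  nodata-aware, reflection padding at edges.
* **GLCM textures**: values are quantised to 32 grey levels over the
  layer's global valid range; per pixel, grey-level pairs co-occurring
  at distance 4 along the four symmetric directions (0°, 45°, 90°,
  135°) within a 3×3 kernel neighbourhood are accumulated symmetrically
  into a normalised co-occurrence distribution, and contrast
  (Σ(i−j)²P), correlation (ΣP(i−μᵢ)(j−μⱼ)/σᵢσⱼ, defined as 0 where
  σᵢσⱼ = 0 so stacks stay dense) and variance (ΣP(i−μ)²) are its
  moments. The implementation accumulates moments from shifted arrays
  without materialising per-pixel matrices; a brute-force
  matrix-building oracle in the test suite pins the definition to
  1e−12.
* **Temporal amplitude**: p90 − p10 of each pixel's valid radar time
  series; nodata below two observations.
* **Terrain**: slope and aspect by Horn's 3×3 weighted finite
  differences; aspect is degrees clockwise from north pointing
  downslope, with flat cells flagged nodata (one consequence: pixels on
  perfectly flat synthetic terrain drop out of prediction, since any
  nodata feature makes a pixel nodata — no imputation).

## Selection and classification

Training pixels are raster cells whose centre lies inside a training
polygon; rows with any nodata feature are dropped with a logged count.
Standardisation subtracts the mean and divides by the population
standard deviation estimated on training pixels only; zero-variance
columns are scaled by 1 and flagged; the parameters are stored and
re-applied to full rasters at prediction time.

RFE drops one feature per iteration (the lowest overall Gini
importance; first such feature on ties), recording stratified 2-fold CV
overall accuracy at every size down to 1. Folds are stratified by
class, seeded, and held fixed along the whole elimination path, so the
curve reflects feature content rather than fold noise. The optimal size
maximises the curve, ties broken toward the smaller subset (parsimony).
CV scoring uses overall accuracy.

The forest uses ntree = 100 trees and mtry = 2 candidate features per
split (the standard reading of "number of splits"), Gini criterion,
seeded. Overall importances are normalised mean decreases in Gini
impurity and sum to 1. Per-class importance uses the product rule
score(c, f) = importance(f) · |mean of standardised f over class-c
training pixels|; the absolute value keeps scores non-negative, and the
class-conditional-mean reading is a documented choice.

The majority filter replaces each pixel by the modal class of its 3×3
neighbourhood in a single pass; nodata neighbours are excluded from the
vote, any tie for the mode retains the centre class, and nodata centres
stay nodata.

## Evaluation

UA is column-wise and PA row-wise correctness of the confusion matrix
(reference in rows); classes with empty columns/rows get undefined
(NaN) UA/PA rather than zeros. The per-class F-score is the harmonic
mean 2·UA·PA/(UA + PA)/100, reported at two decimals. The McNemar
statistic is (f₁₂ − f₂₁)²/(f₁₂ + f₂₁) referred to a chi-squared
distribution with 1 df, without continuity correction; discordant
counts are tallied over shared test points where exactly one map is
correct, excluding points nodata in either map. Improvement cells are
individual UA/PA difference entries (12 classes × 2 metrics per
compared dataset); strict sign is decided with a 1e−9 tolerance.
Areas are pixel counts times the pixel area (0.04 ha at 20 m);
percentages are over mapped (non-nodata) pixels; general-class areas
are sums over their members, so class and general totals conserve
exactly. Rounding to report precision happens only at the reporting
layer.

Published per-class UA/PA, McNemar statistics, reference counts and
class areas for the Greater Amanzule classification ship as CSVs under
`src/peatstack/data/amanzule/` and feed the arithmetic-reproduction
layer (F-score and p-value recovery, improvement-cell counts, area
aggregation).

## Synthetic scenes

The generator emulates the structure the pipeline assumes, on a
desk-scale 2 km × 2 km default scene: truth and optical series on a
200×200 grid at 10 m, radar on the same grid, DEM at 30 m, analysis at
20 m, 24 optical dates, 12 radar dates, 30% cloud per optical date.
These sizes are the package's default study conditions; the class
signatures are declared fixture values (plausible for a humid tropical
coastal landscape), not estimates of any real site's reflectance.

* **DEM**: smoothed Gaussian field plus a northward (inland) trend with
  valley lines carved toward sea level.
* **Class map**: per-class smoothed Gaussian fields plus an
  elevation-suitability term from each signature's preferred elevation
  interval (water ≤ 3 m, peat swamps ≤ 8 m, forest and plantations
  higher), argmax per pixel, with a few deterministic
  proportion-balancing rounds so all twelve classes occupy non-trivial
  shares. Scenes below roughly 80×80 pixels may genuinely miss a class,
  which surfaces as a clear sampling error.
* **Optical**: class mean + seasonal sinusoid + N(0, 0.02) noise,
  clipped to [0, 1]; clouds are contiguous smooth-field blobs that
  brighten all bands and saturate the blue/aerosol/cirrus layers.
* **Radar**: linear-power class mean × Gamma(L, 1/L) multiplicative
  speckle (unit mean, the standard multi-look model), stored in dB.
  The number of looks varies by class (built-up 2 … water 20),
  encoding surface heterogeneity so that texture and amplitude
  features carry class information, as they do over real landscapes.
* **Reference data**: training rectangles placed fully inside
  single-class patches (6×6 truth pixels by default, shrinking for
  fragmented classes), stratified-random test points disjoint from the
  rectangles, labels copied from truth.

What passing synthetic tests show: the operators compute the intended
statistics (pinned by oracles), the pipeline is deterministic under
seeds, irrelevant features are eliminated before informative ones, a
class-specific topographic signal surfaces in the per-class importance
ranking, and richer dataset combinations do not classify worse than
radar alone. What they do not show: performance on real Sentinel/SRTM
imagery — the generator has no atmosphere, no radiative transfer, no
geolocation error, no SAR geometry (layover/shadow), and Gaussian
band noise rather than correlated sensor noise; published headline
accuracies from real imagery are therefore not reproduction targets.

## Degenerate inputs and numerics

Zero-denominator index pixels, all-invalid composite pixels, windows
with no valid member, flat-aspect cells and empty percentile intervals
all resolve to documented nodata or fallback values rather than
errors. Empty test sets, absent classes, unknown tags/bands and
non-georeferenced rasters raise errors naming the offending object.
Quantisation, percentile interpolation and tie-break rules are each
fixed by an oracle-backed test so the conventions cannot drift.
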