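# peatstack

Multi-sensor land-cover classification for tropical peatland mapping:
a tested, reusable implementation of the optical + radar + elevation
pipeline used to map the Greater Amanzule peatland complex on the coast
of Ghana.

Tropical peatlands are hard to map from any single sensor: their swamp
forests look like other closed-canopy forests to optical instruments,
optical imagery is chronically cloud-contaminated in the humid tropics,
and radar alone cannot separate spectrally distinct but structurally
similar covers. The pipeline implemented here fuses an annual Sentinel-2
style optical time series, a dual-polarisation (VV/VH) C-band radar
time series and a digital elevation model into six dataset combinations
(S2, S2+, S1, S1+, S2+S1+, S2+S1+DEM), classifies twelve land-cover
classes — four peatland classes (mangrove swamp, mixed swamp, palm
swamp, bog plain), natural forest, sparse vegetation, three plantation
crops, built-up land, bare surface and water — and quantifies what each
data source contributes.

## The method

1. **Compositing** — per-date cloud scores (mean of per-band linear
   ramps over blue, NIR, SWIR1 and two cirrus-proxy layers) mask cloudy
   pixels; each pixel/band is then summarised by the *mean of the
   observations between the 40th and 60th percentile* of its valid time
   series, a robust composite that rejects residual haze and
   phenological extremes. Everything is resampled to a common 20 m grid
   by nearest neighbour.
2. **Feature extraction** — 36 candidate layers: the 10 optical bands;
   ten vegetation indices (NDVI, NDWI, LSWI, EVI, ARVI, NBR, NBR2,
   GNDVI, S2REP, MSAVI2); 5×5 moving-window standard deviations of
   NDVI, VV and VH; GLCM contrast, correlation and variance of VV and
   VH (offset distance 4, 3×3 kernel); radar temporal amplitudes
   (p90 − p10 of the VV and VH series); and elevation, slope and aspect
   (Horn's method).
3. **Feature selection** — features are standardised (zero mean, unit
   variance) and reduced by recursive feature elimination: a random
   forest is fitted, the feature with the lowest Gini importance is
   dropped, and the stratified 2-fold cross-validated accuracy is
   recorded at every subset size; the subset maximising the curve wins.
4. **Classification** — a random forest with ntree = 100 trees and
   mtry = 2 candidate features per split, followed by a 3×3 majority
   filter. Per-class feature importance is the product of the overall
   Gini importance and the absolute standardised class mean of the
   feature.
5. **Evaluation** — confusion matrices with user's/producer's/overall
   accuracy, per-class F-scores (harmonic mean of UA and PA), pairwise
   McNemar chi-squared tests on discordant test points
   (χ² = (f₁₂ − f₂₁)²/(f₁₂ + f₂₁), 1 df), UA/PA improvement tables and
   per-class area accounting (a 20 m pixel is 0.04 ha).

Because the original satellite archive cannot be shipped, the package
includes a seeded synthetic-scene generator that reproduces the
statistical structure the pipeline relies on — a patchy class mosaic
conditioned on a coastal DEM (water and peat swamps in valley bottoms),
Gaussian-noise optical series with contiguous bright cloud blobs, and
Gamma-speckled radar series — so every stage runs and is tested without
any download.

## Worked example

```python
from peatstack.synthetic import SceneConfig, generate_scene
from peatstack.compositing import CompositeSpec, mask_clouds, percentile_range_composite
from peatstack.features import assemble_combination
from peatstack.selection import extract_training_pixels, standardize
from peatstack.classify import train_rf, predict_map, majority_filter
from peatstack.evaluate import confusion

scene = generate_scene(SceneConfig(seed=7))          # 2 km x 2 km, 12 classes
optical = percentile_range_composite(
    mask_clouds(scene.optical_series, 0.5), CompositeSpec())
radar = percentile_range_composite(scene.radar_series, CompositeSpec())

feats = assemble_combination("S2+S1+DEM", optical=optical, radar=radar,
                             radar_series=scene.radar_series, dem=scene.dem)
table = standardize(extract_training_pixels(feats, scene.reference))
model = train_rf(table, ntree=100, mtry=2, seed=7)
cmap = majority_filter(predict_map(model, feats))
report = confusion(cmap, scene.reference.testing)
print(f"held-out OA {report.oa:.2f}% on {report.n_points} test points")
```

prints

```
held-out OA 94.98% on 558 test points
```

i.e. the full optical–radar–DEM stack recovers the synthetic truth map
with ~95% overall accuracy on 558 independent test points (42 of the
600 sampled points land on nodata map pixels — mostly flat cells whose
aspect is undefined — and are dropped, with the count logged). Radar
alone (`"S1"`) reaches 60.7% on the same scene — the qualitative
ordering the multi-sensor design exists to demonstrate.

The same experiment is available from the shell:

```bash
peatstack run --seed 7 --out runs/demo        # full six-combination experiment
```

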