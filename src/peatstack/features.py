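"""Candidate feature computation and dataset-combination assembly.

Thirty-six candidate layers feed the classifier: the ten optical analysis
bands, ten vegetation indices, nine texture features (windowed standard
deviations of NDVI/VV/VH and GLCM contrast/correlation/variance of VV and
VH), two radar temporal-amplitude features and three terrain features.
They are arranged into six dataset combinations (S2, S2+, S1, S1+,
S2+S1+, S2+S1+DEM) for comparative classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from peatstack.compositing import (nan_percentile, resample_nearest,
                                   resample_stack_nearest)
from peatstack.grids import FeatureStack, ImageTimeSeries, RasterGrid, SceneStack

#: The ten optical analysis bands, in wavelength order.
OPTICAL_BANDS: tuple[str, ...] = (
    "Blue", "Green", "Red", "RedEdge1", "RedEdge2", "RedEdge3",
    "NIR", "RedEdge4", "SWIR1", "SWIR2",
)

VEGETATION_INDICES: tuple[str, ...] = (
    "NDVI", "NDWI", "LSWI", "EVI", "ARVI", "NBR", "NBR2", "GNDVI",
    "S2REP", "MSAVI2",
)

#: Feature lists of the six dataset combinations.
COMBINATIONS: dict[str, tuple[str, ...]] = {
    "S2": OPTICAL_BANDS,
    "S2+": OPTICAL_BANDS + (
        "NDVI", "GNDVI", "LSWI", "S2REP", "NDWI", "NBR", "NBR2", "EVI",
        "ARVI", "MSAVI2", "NDVI_stdDev",
    ),
    "S1": ("VH", "VV"),
    "S1+": (
        "VH", "VV", "VV_correlation", "VV_variance", "VV_contrast",
        "VH_correlation", "VH_variance", "VH_contrast", "VV_stdDev",
        "VH_stdDev", "VV_amplitude", "VH_amplitude",
    ),
}
COMBINATIONS["S2+S1+"] = COMBINATIONS["S2+"] + COMBINATIONS["S1+"]
COMBINATIONS["S2+S1+DEM"] = COMBINATIONS["S2+S1+"] + ("Elevation", "Slope", "Aspect")


def _nd(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Normalised difference (a-b)/(a+b) with zero denominators as NaN."""
    den = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den != 0, (a - b) / den, np.nan)
    return out


def vegetation_indices(optical: SceneStack) -> FeatureStack:
    """The ten vegetation indices, computed pixel-wise.

    NDVI, NDWI, LSWI, NBR, NBR2 and GNDVI are normalised differences;
    EVI and ARVI are atmosphere-resistant ratios; S2REP estimates the
    red-edge inflection wavelength (nm); MSAVI2 is the self-adjusting
    soil-corrected index. Zero-denominator pixels become nodata.
    """
    b = {name: optical.band(name).astype(float) for name in OPTICAL_BANDS}
    blue, green, red = b["Blue"], b["Green"], b["Red"]
    re1, re2, re3 = b["RedEdge1"], b["RedEdge2"], b["RedEdge3"]
    nir, swir1, swir2 = b["NIR"], b["SWIR1"], b["SWIR2"]

    with np.errstate(divide="ignore", invalid="ignore"):
        evi_den = nir + 6.0 * red - 7.5 * blue + 1.0
        evi = np.where(evi_den != 0, 2.5 * (nir - red) / evi_den, np.nan)
        arvi = _nd(nir, 2.0 * red - blue)
        s2rep_den = re2 - re1
        s2rep = np.where(
            s2rep_den != 0,
            705.0 + 35.0 * ((re3 + red) / 2.0 - re1) / s2rep_den,
            np.nan,
        )
        disc = (2.0 * nir + 1.0) ** 2 - 8.0 * (nir - red)
        msavi2 = np.where(
            disc >= 0, (2.0 * nir + 1.0 - np.sqrt(np.maximum(disc, 0.0))) / 2.0, np.nan
        )

    feats = {
        "NDVI": _nd(nir, red),
        "NDWI": _nd(green, nir),
        "LSWI": _nd(nir, swir1),
        "EVI": evi,
        "ARVI": arvi,
        "NBR": _nd(nir, swir2),
        "NBR2": _nd(swir1, swir2),
        "GNDVI": _nd(nir, green),
        "S2REP": s2rep,
        "MSAVI2": msavi2,
    }
    prov = {k: "vegetation index from optical composite" for k in feats}
    return FeatureStack(feats, optical.pixel_size, optical.origin, provenance=prov)


def window_stddev(layer: np.ndarray | RasterGrid, window: int = 5) -> np.ndarray | RasterGrid:
    """Moving-window population standard deviation (nodata-aware).

    Edges are handled by reflection padding; NaN members are excluded from
    each window's statistics (a window with no valid member yields NaN).
    """
    grid = layer if isinstance(layer, RasterGrid) else None
    arr = np.asarray(layer.data if grid is not None else layer, dtype=float)
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    if window > min(arr.shape):
        raise ValueError("window larger than raster")
    r = window // 2
    padded = np.pad(arr, r, mode="reflect")
    windows = sliding_window_view(padded, (window, window))
    valid = ~np.isnan(windows)
    n = valid.sum(axis=(-2, -1))
    s = np.nansum(windows, axis=(-2, -1))
    ss = np.nansum(windows**2, axis=(-2, -1))
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.divide(s, n, out=np.full(n.shape, np.nan), where=n > 0)
        var = np.divide(ss, n, out=np.full(n.shape, np.nan), where=n > 0) - mean**2
    out = np.sqrt(np.maximum(var, 0.0))
    if grid is not None:
        return RasterGrid(out, grid.pixel_size, grid.origin)
    return out


@dataclass(frozen=True)
class GLCMSpec:
    """Grey-level co-occurrence texture parameters.

    A 3x3 kernel of pixels around each centre contributes co-occurring
    pairs at ``distance`` pixels along four symmetric directions (0, 45,
    90, 135 degrees); values are first quantised to ``levels`` grey
    levels over the layer's global valid range. The effective context
    window is the kernel enlarged by the offset distance.
    """

    kernel: int = 3
    distance: int = 4
    levels: int = 32
    statistics: tuple[str, ...] = ("contrast", "correlation", "variance")

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("need at least 2 grey levels")
        if self.kernel % 2 == 0 or self.kernel < 1:
            raise ValueError("kernel must be odd and positive")
        if self.distance < 1:
            raise ValueError("offset distance must be >= 1")
        bad = set(self.statistics) - {"contrast", "correlation", "variance"}
        if bad:
            raise ValueError(f"unknown GLCM statistics: {sorted(bad)}")

    @property
    def offsets(self) -> tuple[tuple[int, int], ...]:
        d = self.distance
        return ((0, d), (d, 0), (d, d), (d, -d))


def quantise(layer: np.ndarray, levels: int) -> np.ndarray:
    """Linear rescale of the layer's global valid range to integer grey
    levels 0..levels-1 (NaN stays NaN, encoded as -1)."""
    arr = np.asarray(layer, dtype=float)
    valid = np.isfinite(arr)
    out = np.full(arr.shape, -1, dtype=np.int64)
    if not valid.any():
        return out
    lo, hi = arr[valid].min(), arr[valid].max()
    if hi == lo:
        out[valid] = 0
        return out
    q = np.floor((arr[valid] - lo) / (hi - lo) * levels).astype(np.int64)
    out[valid] = np.clip(q, 0, levels - 1)
    return out


def glcm_features(
    layer: np.ndarray | RasterGrid,
    spec: GLCMSpec | None = None,
    prefix: str | None = None,
) -> dict[str, np.ndarray] | FeatureStack:
    """Per-pixel GLCM contrast, correlation and variance.

    Per pixel, the grey-level pairs co-occurring at the spec's offsets
    within the kernel neighbourhood are accumulated symmetrically into a
    normalised co-occurrence distribution; the three texture statistics
    are its moments:

        contrast     = sum_{i,j} (i-j)^2 P(i,j)
        correlation  = sum_{i,j} P(i,j) (i-mu_i)(j-mu_j) / (sigma_i sigma_j)
        variance     = sum_{i,j} P(i,j) (i-mu)^2

    Correlation is defined as 0 where sigma_i*sigma_j = 0 so feature
    stacks stay dense. Pixels with no valid pair yield NaN. The moments
    are accumulated directly from shifted arrays (no per-pixel matrix is
    materialised); symmetry makes mu_i = mu_j = mu.
    """
    spec = spec if spec is not None else GLCMSpec()
    grid = layer if isinstance(layer, RasterGrid) else None
    arr = np.asarray(layer.data if grid is not None else layer, dtype=float)
    q = quantise(arr, spec.levels).astype(float)
    q[q < 0] = np.nan

    kr = spec.kernel // 2
    pad = kr + spec.distance
    qp = np.pad(q, pad, mode="reflect")
    rows, cols = arr.shape

    n = np.zeros((rows, cols))
    s1 = np.zeros((rows, cols))   # sum of i over ordered symmetric pairs
    s2 = np.zeros((rows, cols))   # sum of i^2
    sp = np.zeros((rows, cols))   # sum of i*j

    def shifted(dy: int, dx: int) -> np.ndarray:
        return qp[pad + dy: pad + dy + rows, pad + dx: pad + dx + cols]

    for ky in range(-kr, kr + 1):
        for kx in range(-kr, kr + 1):
            a = shifted(ky, kx)
            for dy, dx in spec.offsets:
                b = shifted(ky + dy, kx + dx)
                ok = ~np.isnan(a) & ~np.isnan(b)
                av = np.where(ok, a, 0.0)
                bv = np.where(ok, b, 0.0)
                # add both orders so the distribution is symmetric
                n += 2 * ok
                s1 += av + bv
                s2 += av**2 + bv**2
                sp += 2 * av * bv

    with np.errstate(invalid="ignore", divide="ignore"):
        nn = np.where(n > 0, n, np.nan)
        mu = s1 / nn
        var = s2 / nn - mu**2
        var = np.maximum(var, 0.0)
        contrast = (2.0 * s2 - 2.0 * sp) / nn
        cov = sp / nn - mu**2
        correlation = np.where(var > 0, cov / np.where(var > 0, var, 1.0), 0.0)
        correlation = np.where(np.isnan(nn), np.nan, correlation)

    stats = {"contrast": contrast, "correlation": correlation, "variance": var}
    out = {k: stats[k] for k in spec.statistics}
    if prefix is not None:
        out = {f"{prefix}_{k}": v for k, v in out.items()}
    if grid is not None:
        prov = {k: f"GLCM texture, distance {spec.distance}, {spec.levels} levels"
                for k in out}
        return FeatureStack(out, grid.pixel_size, grid.origin, provenance=prov)
    return out


def temporal_amplitude(series: ImageTimeSeries, band: str) -> RasterGrid:
    """Per-pixel amplitude between the 10th and 90th percentile of the
    valid time series (linear-interpolation percentiles); always >= 0.

    Pixels with fewer than two valid observations become nodata.
    """
    cube = series.band_cube(band)
    n_valid = np.sum(~np.isnan(cube), axis=0)
    with np.errstate(invalid="ignore"):
        p10 = nan_percentile(cube, 10)
        p90 = nan_percentile(cube, 90)
    amp = p90 - p10
    amp[n_valid < 2] = np.nan
    return RasterGrid(amp, series.pixel_size, series.origin)


def terrain_features(dem: RasterGrid) -> FeatureStack:
    """Elevation, slope and aspect from a DEM on square pixels.

    Slope (degrees) and aspect (degrees clockwise from north, pointing
    downslope) come from Horn's 3x3 weighted finite differences with
    reflection padding at edges. Flat cells (zero gradient) get NaN
    aspect.
    """
    z = np.asarray(dem.data, dtype=float)
    cell = dem.pixel_size
    zp = np.pad(z, 1, mode="reflect")

    nw, n_, ne = zp[:-2, :-2], zp[:-2, 1:-1], zp[:-2, 2:]
    w_, e_ = zp[1:-1, :-2], zp[1:-1, 2:]
    sw, s_, se = zp[2:, :-2], zp[2:, 1:-1], zp[2:, 2:]

    dzdx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8.0 * cell)
    # northward derivative: rows increase southward
    dzdy = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8.0 * cell)

    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    flat = (dzdx == 0) & (dzdy == 0)
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    aspect = np.where(flat, np.nan, aspect)

    feats = {"Elevation": z, "Slope": slope, "Aspect": aspect}
    prov = {
        "Elevation": "DEM (m)",
        "Slope": "Horn 3x3 finite differences (degrees)",
        "Aspect": "degrees clockwise from north, flat cells nodata",
    }
    return FeatureStack(feats, dem.pixel_size, dem.origin, provenance=prov)


def assemble_combination(
    tag: str,
    optical: SceneStack | None = None,
    radar: SceneStack | None = None,
    radar_series: ImageTimeSeries | None = None,
    dem: RasterGrid | None = None,
    pixel_size: float = 20.0,
    glcm_spec: GLCMSpec | None = None,
) -> FeatureStack:
    """Build exactly the feature list of one dataset combination.

    ``optical`` and ``radar`` are cloud-free composites on their native
    grids; all layers are brought to the common analysis grid by
    nearest-neighbour resampling. Texture features are computed on the
    analysis grid; radar temporal amplitudes on the native radar grid and
    then resampled.
    """
    if tag not in COMBINATIONS:
        raise ValueError(f"unknown combination tag {tag!r}")
    wanted = COMBINATIONS[tag]

    need_optical = any(f in OPTICAL_BANDS or f in VEGETATION_INDICES
                       or f == "NDVI_stdDev" for f in wanted)
    need_radar = any(f.startswith(("VV", "VH")) for f in wanted)
    need_amp = any(f.endswith("_amplitude") for f in wanted)
    need_dem = any(f in ("Elevation", "Slope", "Aspect") for f in wanted)

    missing = []
    if need_optical and optical is None:
        missing.append("optical composite")
    if need_radar and radar is None:
        missing.append("radar composite")
    if need_amp and radar_series is None:
        missing.append("radar time series")
    if need_dem and dem is None:
        missing.append("DEM")
    if missing:
        raise ValueError(f"combination {tag!r} missing inputs: {missing}")

    # common analysis-grid shape from the finest-extent available input
    ref = optical if optical is not None else radar
    if ref is not None:
        rows, cols = ref.shape
        target_shape = (
            max(1, int(np.ceil(rows * ref.pixel_size / pixel_size - 1e-9))),
            max(1, int(np.ceil(cols * ref.pixel_size / pixel_size - 1e-9))),
        )
    else:
        r, c = dem.shape
        target_shape = (
            max(1, int(np.ceil(r * dem.pixel_size / pixel_size - 1e-9))),
            max(1, int(np.ceil(c * dem.pixel_size / pixel_size - 1e-9))),
        )

    layers: dict[str, np.ndarray] = {}
    prov: dict[str, str] = {}

    if need_optical:
        opt20 = resample_stack_nearest(optical, pixel_size, target_shape)
        for name in OPTICAL_BANDS:
            layers[name] = opt20.band(name).astype(float)
            prov[name] = "optical composite band"
        vi = vegetation_indices(opt20)
        for name in VEGETATION_INDICES:
            layers[name] = vi.layer(name)
            prov[name] = vi.provenance[name]
        if "NDVI_stdDev" in wanted:
            layers["NDVI_stdDev"] = window_stddev(layers["NDVI"], 5)
            prov["NDVI_stdDev"] = "5x5 moving-window std dev of NDVI"

    if need_radar:
        rad20 = resample_stack_nearest(radar, pixel_size, target_shape)
        for pol in ("VH", "VV"):
            layers[pol] = rad20.band(pol).astype(float)
            prov[pol] = "radar composite backscatter (dB)"
        for pol in ("VV", "VH"):
            if f"{pol}_stdDev" in wanted:
                layers[f"{pol}_stdDev"] = window_stddev(layers[pol], 5)
                prov[f"{pol}_stdDev"] = f"5x5 moving-window std dev of {pol}"
            if f"{pol}_contrast" in wanted:
                tex = glcm_features(layers[pol], glcm_spec, prefix=pol)
                for k, v in tex.items():
                    layers[k] = v
                    prov[k] = f"GLCM texture of {pol}"

    if need_amp:
        for pol in ("VV", "VH"):
            amp = temporal_amplitude(radar_series, pol)
            amp20 = resample_nearest(amp, pixel_size, target_shape)
            layers[f"{pol}_amplitude"] = amp20.data
            prov[f"{pol}_amplitude"] = f"p90 - p10 of the {pol} time series"

    if need_dem:
        terrain = terrain_features(dem)
        for name in ("Elevation", "Slope", "Aspect"):
            rg = RasterGrid(terrain.layer(name), dem.pixel_size, dem.origin)
            layers[name] = resample_nearest(rg, pixel_size, target_shape).data
            prov[name] = terrain.provenance[name]

    origin = (optical or radar).origin if (optical or radar) else dem.origin
    ordered = {name: layers[name] for name in wanted}
    return FeatureStack(ordered, pixel_size, origin, tag=tag,
                        provenance={n: prov[n] for n in wanted})
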