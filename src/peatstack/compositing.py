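"""Cloud scoring, masking and percentile-range compositing.

An annual stack of optical scenes is reduced to a single cloud-free
composite: per pixel and band, observations between the 40th and 60th
percentile of the valid time series are averaged. The narrow percentile
window rejects residual cloud, haze and phenological extremes that survive
the explicit cloud mask. Radar stacks are composited with the same
operator but without cloud masking (radar is all-weather).

The cloud score is a mean of per-band linear ramps: each of five bands
(blue, NIR, SWIR1 and two cirrus-proxy layers) is rescaled between a
"clear" anchor (score 0) and a "cloudy" anchor (score 1) and the five
ramp values averaged. The score is monotone non-decreasing in every
input band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from peatstack.grids import ImageTimeSeries, RasterGrid, SceneStack

#: Per-band (clear, cloudy) reflectance anchors of the cloud score ramps.
#: Anchored so typical land/water surfaces score near 0 and optically thick
#: cloud near 1; the cirrus proxies respond to thin cirrus.
CLOUD_SCORE_ANCHORS: dict[str, tuple[float, float]] = {
    "Blue": (0.1, 0.3),
    "Aerosol": (0.1, 0.3),
    "NIR": (0.25, 0.8),
    "SWIR1": (0.1, 0.4),
    "Cirrus": (0.01, 0.1),
}

DEFAULT_CLOUD_THRESHOLD = 0.5


@dataclass(frozen=True)
class CompositeSpec:
    """Parameters of the percentile-range composite.

    p_lo/p_hi bound the percentile window (defaults 40 and 60);
    percentiles use the ``interpolation`` rule ("linear" interpolates
    between order statistics). Pixels with fewer than ``min_valid``
    usable observations become nodata.
    """

    p_lo: float = 40.0
    p_hi: float = 60.0
    interpolation: str = "linear"
    min_valid: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.p_lo <= self.p_hi <= 100):
            raise ValueError("require 0 <= p_lo <= p_hi <= 100")
        if self.min_valid < 1:
            raise ValueError("min_valid must be >= 1")


def _ramp(values: np.ndarray, clear: float, cloudy: float) -> np.ndarray:
    return np.clip((values - clear) / (cloudy - clear), 0.0, 1.0)


def nan_percentile(cube: np.ndarray, q: float) -> np.ndarray:
    """Linear-interpolation percentile along axis 0, ignoring NaNs.

    Vectorised over the trailing axes (numpy's nanpercentile degrades to
    a per-slice loop once NaNs are present, which is far too slow for
    full scenes). All-NaN slices yield NaN.
    """
    data = np.sort(cube, axis=0)  # NaNs sort to the end
    n = np.sum(~np.isnan(cube), axis=0)
    rank = q / 100.0 * np.maximum(n - 1, 0)
    lo = np.floor(rank).astype(int)
    hi = np.ceil(rank).astype(int)
    lo_v = np.take_along_axis(data, lo[None], axis=0)[0]
    hi_v = np.take_along_axis(data, hi[None], axis=0)[0]
    frac = rank - lo
    out = lo_v + (hi_v - lo_v) * frac
    return np.where(n > 0, out, np.nan)


def cloud_score(
    stack: SceneStack,
    anchors: dict[str, tuple[float, float]] | None = None,
) -> RasterGrid:
    """Per-pixel cloud likelihood in [0, 1] as the mean of per-band ramps."""
    anchors = anchors if anchors is not None else CLOUD_SCORE_ANCHORS
    ramps = []
    for band, (clear, cloudy) in anchors.items():
        ramps.append(_ramp(stack.band(band).astype(float), clear, cloudy))
    score = np.mean(ramps, axis=0)
    return RasterGrid(score, stack.pixel_size, stack.origin)


def mask_clouds(
    series: ImageTimeSeries,
    threshold: float = DEFAULT_CLOUD_THRESHOLD,
    anchors: dict[str, tuple[float, float]] | None = None,
) -> ImageTimeSeries:
    """Invalidate pixels whose cloud score is >= threshold.

    Band values are untouched; only the validity masks are updated.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    out = []
    for stack in series:
        score = cloud_score(stack, anchors).data
        new_mask = stack.valid_mask() & (score < threshold)
        out.append(stack.with_mask(new_mask))
    return ImageTimeSeries(out)


def _composite_cube(cube: np.ndarray, spec: CompositeSpec) -> np.ndarray:
    """Percentile-range composite of one (time, rows, cols) cube.

    Invalid observations are NaN. Per pixel: take the mean of all valid
    observations v with P(p_lo) <= v <= P(p_hi); if the closed interval
    captures none, take the single observation nearest the interval
    midpoint (ties toward the smaller value).
    """
    if spec.interpolation != "linear":
        raise ValueError("only linear percentile interpolation is supported")
    n_valid = np.sum(~np.isnan(cube), axis=0)
    with np.errstate(invalid="ignore"):
        # all-NaN slices produce NaN percentiles; silenced and handled below
        lo = nan_percentile(cube, spec.p_lo)
        hi = nan_percentile(cube, spec.p_hi)
        inside = (cube >= lo) & (cube <= hi)
        count = inside.sum(axis=0)
        total = np.nansum(np.where(inside, cube, 0.0), axis=0)
        out = np.divide(total, count, out=np.full(count.shape, np.nan), where=count > 0)

        # empty-interval fallback: observation nearest the interval midpoint
        empty = (count == 0) & (n_valid > 0)
        if np.any(empty):
            mid = (lo + hi) / 2.0
            dist = np.abs(cube - mid)
            dist = np.where(np.isnan(cube), np.inf, dist)
            min_dist = dist.min(axis=0)
            candidates = np.where(dist <= min_dist + 1e-12, cube, np.inf)
            out = np.where(empty, candidates.min(axis=0), out)

    out[n_valid < spec.min_valid] = np.nan
    return out


def percentile_range_composite(
    series: ImageTimeSeries, spec: CompositeSpec | None = None
) -> SceneStack:
    """Reduce a time series to one composite stack (nodata = NaN)."""
    spec = spec if spec is not None else CompositeSpec()
    if len(series) == 0:
        raise ValueError("cannot composite an empty series")
    bands = {
        name: _composite_cube(series.band_cube(name), spec)
        for name in series.band_names
    }
    return SceneStack(bands, series.pixel_size, series.origin)


def _nearest_indices(
    n_src: int, src_size: float, dst_size: float, n_out: int | None = None
) -> np.ndarray:
    if n_out is None:
        n_out = max(1, int(np.ceil(n_src * src_size / dst_size - 1e-9)))
    centres = (np.arange(n_out) + 0.5) * dst_size
    return np.clip(np.floor(centres / src_size).astype(int), 0, n_src - 1)


def resample_nearest(
    raster: RasterGrid,
    target_pixel_size: float,
    out_shape: tuple[int, int] | None = None,
) -> RasterGrid:
    """Nearest-neighbour resample to a grid aligned to the source origin.

    Each output pixel takes the value of the source pixel containing the
    output pixel centre, so categorical rasters never acquire new
    categories and no interpolation occurs. ``out_shape`` forces the
    output dimensions (centres beyond the source extent clip to the edge
    pixel); by default the output covers the source extent.
    """
    if not target_pixel_size > 0:
        raise ValueError("target pixel size must be positive")
    rows, cols = raster.shape
    ridx = _nearest_indices(rows, raster.pixel_size, target_pixel_size,
                            out_shape[0] if out_shape else None)
    cidx = _nearest_indices(cols, raster.pixel_size, target_pixel_size,
                            out_shape[1] if out_shape else None)
    data = raster.data[np.ix_(ridx, cidx)]
    return RasterGrid(data, target_pixel_size, raster.origin, raster.nodata)


def resample_stack_nearest(
    stack: SceneStack,
    target_pixel_size: float,
    out_shape: tuple[int, int] | None = None,
) -> SceneStack:
    """Nearest-neighbour resample of every band (and the mask) of a stack."""
    if not target_pixel_size > 0:
        raise ValueError("target pixel size must be positive")
    rows, cols = stack.shape
    ridx = _nearest_indices(rows, stack.pixel_size, target_pixel_size,
                            out_shape[0] if out_shape else None)
    cidx = _nearest_indices(cols, stack.pixel_size, target_pixel_size,
                            out_shape[1] if out_shape else None)
    sel = np.ix_(ridx, cidx)
    bands = {k: v[sel] for k, v in stack.bands.items()}
    mask = stack.mask[sel] if stack.mask is not None else None
    return SceneStack(bands, target_pixel_size, stack.origin, mask, stack.timestamp)
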