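"""Seeded synthetic multi-sensor scenes with known ground truth.

The generator emulates the statistical structure the classification
pipeline assumes on a low-lying coastal peatland landscape: a patchy
class mosaic conditioned on topography (water and peat swamps in valley
bottoms, plantations and forest on higher ground), an annual optical
reflectance time series with additive Gaussian noise, a seasonal
sinusoid and contiguous bright cloud blobs, a radar backscatter series
with multiplicative Gamma speckle of unit mean, and a smooth DEM rising
inland with carved valley lines. Reference data are sampled from the
truth map as training rectangles and stratified-random test points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from peatstack.catalogue import ClassCatalogue, default_catalogue
from peatstack.compositing import resample_nearest
from peatstack.features import OPTICAL_BANDS
from peatstack.grids import ImageTimeSeries, RasterGrid, SceneStack

from shapely.geometry import Point, box

#: Extra optical layers used only for cloud detection (aerosol and cirrus
#: proxies), stacked alongside the ten analysis bands.
CIRRUS_PROXY_BANDS: tuple[str, ...] = ("Aerosol", "Cirrus")


@dataclass(frozen=True)
class ClassSignature:
    """Spectral / backscatter / topographic signature of one class.

    optical_mean and optical_sd are per-band reflectances in [0, 1] for
    the ten analysis bands (wavelength order); sar_mean_db gives mean VV
    and VH backscatter in dB; speckle_looks controls multiplicative
    Gamma speckle variance (larger = smoother); elevation_range_m is the
    elevation interval where the class preferentially occurs;
    seasonal_amplitude is the per-band amplitude of an annual sinusoid.
    """

    name: str
    optical_mean: tuple[float, ...]
    optical_sd: tuple[float, ...]
    sar_mean_db: tuple[float, float]
    speckle_looks: int = 5
    elevation_range_m: tuple[float, float] = (0.0, 50.0)
    seasonal_amplitude: tuple[float, ...] = tuple([0.0] * 10)

    def __post_init__(self) -> None:
        if len(self.optical_mean) != len(OPTICAL_BANDS):
            raise ValueError(f"{self.name}: need {len(OPTICAL_BANDS)} optical means")
        if any(not 0 <= m <= 1 for m in self.optical_mean):
            raise ValueError(f"{self.name}: optical means must lie in [0, 1]")
        if any(s < 0 for s in self.optical_sd):
            raise ValueError(f"{self.name}: optical sd must be >= 0")
        if self.speckle_looks < 1:
            raise ValueError(f"{self.name}: speckle looks must be >= 1")
        lo, hi = self.elevation_range_m
        if lo > hi:
            raise ValueError(f"{self.name}: elevation range low > high")


def _sig(name, mean, sar, elev, sd=0.02, looks=5, amp=0.01):  # noqa: D103
    return ClassSignature(
        name=name,
        optical_mean=tuple(mean),
        optical_sd=tuple([sd] * 10),
        sar_mean_db=sar,
        speckle_looks=looks,
        elevation_range_m=elev,
        seasonal_amplitude=tuple([amp] * 10),
    )


def default_signatures() -> dict[str, ClassSignature]:
    """Fixture signatures for the 12 classes.

    Declared fixture values chosen for plausible separability of a humid
    tropical coastal landscape (dark wet swamp forest, bright built-up
    and bare surfaces, very dark smooth water in radar), not estimates
    of any real site's reflectance.
    """
    # band order: Blue, Green, Red, RE1, RE2, RE3, NIR, RE4, SWIR1, SWIR2
    # looks encode surface heterogeneity: built-up is rough (few effective
    # looks), open water is smooth (many)
    table = {
        "mangrove swamp":   ([.03, .05, .04, .08, .18, .22, .25, .26, .10, .05], (-9.0, -15.0), (0, 6), 6),
        "mixed swamp":      ([.04, .06, .05, .09, .22, .27, .30, .31, .12, .06], (-8.0, -13.5), (0, 8), 5),
        "palm swamp":       ([.04, .07, .05, .10, .24, .30, .34, .35, .14, .07], (-7.5, -12.5), (0, 8), 5),
        "bog plain":        ([.05, .08, .07, .12, .22, .25, .28, .29, .18, .10], (-11.0, -17.0), (0, 7), 9),
        "natural forest":   ([.03, .06, .04, .09, .25, .32, .38, .39, .13, .06], (-7.0, -12.0), (15, 50), 4),
        "sparse vegetation":([.07, .10, .11, .15, .22, .25, .27, .28, .25, .16], (-10.0, -16.0), (8, 35), 3),
        "coconut":          ([.04, .07, .06, .11, .23, .28, .33, .34, .16, .08], (-8.5, -14.0), (5, 20), 5),
        "rubber":           ([.04, .07, .05, .10, .26, .33, .36, .37, .15, .07], (-8.0, -13.0), (12, 35), 4),
        "oil palm":         ([.04, .08, .06, .11, .27, .34, .37, .38, .17, .09], (-7.5, -12.8), (8, 25), 4),
        "built-up":         ([.12, .14, .15, .17, .20, .22, .23, .23, .26, .24], (-5.0, -11.0), (5, 30), 2),
        "bare surface":     ([.10, .13, .16, .20, .24, .26, .28, .29, .32, .28], (-12.0, -19.0), (5, 30), 12),
        "water":            ([.06, .08, .05, .04, .03, .02, .02, .02, .01, .01], (-20.0, -26.0), (0, 3), 20),
    }
    return {
        name: _sig(name, mean, sar, elev, looks=looks)
        for name, (mean, sar, elev, looks) in table.items()
    }


@dataclass
class SceneConfig:
    """Configuration of one synthetic scene.

    The truth map and optical series live on a (rows x cols) grid at
    ``pixel_size`` metres; radar shares that grid; the DEM is generated
    at ``dem_pixel_size`` over the same extent. Defaults give a 2 km x
    2 km scene with 24 optical and 12 radar dates and 30% cloud per
    optical date.
    """

    rows: int = 200
    cols: int = 200
    pixel_size: float = 10.0
    dem_pixel_size: float = 30.0
    n_optical_dates: int = 24
    n_radar_dates: int = 12
    cloud_fraction: float = 0.3
    seed: int = 0
    patch_scale: float = 12.0
    signatures: dict[str, ClassSignature] = field(default_factory=default_signatures)
    catalogue: ClassCatalogue = field(default_factory=default_catalogue)

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if not 0 <= self.cloud_fraction <= 1:
            raise ValueError("cloud fraction must lie in [0, 1]")
        unknown = set(self.signatures) - set(self.catalogue.classes)
        if unknown:
            raise ValueError(f"signatures for unknown classes: {sorted(unknown)}")

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(c for c in self.catalogue.classes if c in self.signatures)


@dataclass
class ReferenceSet:
    """Training polygons and testing points with catalogue labels."""

    training: list[tuple[object, str]] = field(default_factory=list)
    testing: list[tuple[object, str]] = field(default_factory=list)

    def training_classes(self) -> set[str]:
        return {c for _, c in self.training}

    def testing_classes(self) -> set[str]:
        return {c for _, c in self.testing}


@dataclass
class LabeledScene:
    """A complete synthetic scene: truth, imagery, DEM and reference data."""

    truth: RasterGrid                  # integer class indices
    optical_series: ImageTimeSeries
    radar_series: ImageTimeSeries
    dem: RasterGrid
    reference: ReferenceSet
    cloud_truth: list[np.ndarray]      # per optical date, True = cloud
    config: SceneConfig


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], scale: float) -> np.ndarray:
    """Unit-variance smoothed Gaussian random field."""
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, sigma=scale, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_dem(config: SceneConfig) -> RasterGrid:
    """Smooth DEM rising inland with carved valley lines.

    The coast sits at the southern (bottom) edge; elevation trends
    northward, with low-frequency roughness and valley lines carved down
    toward sea level, emulating a low-lying coastal plain drained by
    rivers.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    extent_y = config.rows * config.pixel_size
    extent_x = config.cols * config.pixel_size
    rows = max(2, int(np.ceil(extent_y / config.dem_pixel_size - 1e-9)))
    cols = max(2, int(np.ceil(extent_x / config.dem_pixel_size - 1e-9)))

    scale = max(1.0, config.patch_scale * config.pixel_size / config.dem_pixel_size)
    rough = _smooth_field(rng, (rows, cols), scale) * 4.0
    inland = np.linspace(1.0, 0.0, rows)[:, None] * np.ones((1, cols)) * 35.0

    # valley lines: low quantiles of a second smooth field, carved deeper inland
    valley_field = _smooth_field(rng, (rows, cols), scale * 1.5)
    depth = np.clip(np.quantile(valley_field, 0.25) - valley_field, 0, None)
    carve = depth / max(depth.max(), 1e-9) * 30.0

    z = np.clip(inland + rough - carve, 0.0, None)
    return RasterGrid(z, config.dem_pixel_size, origin=(0.0, 0.0))


def _elevation_suitability(elev: np.ndarray, rng_m: tuple[float, float]) -> np.ndarray:
    lo, hi = rng_m
    mid = (lo + hi) / 2.0
    half = max((hi - lo) / 2.0, 1e-6)
    return 1.0 - ((elev - mid) / half) ** 2


def generate_class_map(config: SceneConfig, dem: RasterGrid | None = None) -> RasterGrid:
    """Patchy categorical class map conditioned on the DEM.

    Per class, a smoothed Gaussian field (correlation length
    ``patch_scale`` pixels) is combined with an elevation-suitability
    term from the class signature; each pixel takes the argmax class. A
    few rounds of proportion balancing nudge per-class biases so every
    class occupies a non-trivial share of the scene.
    """
    if dem is None:
        dem = generate_dem(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    shape = (config.rows, config.cols)
    elev = resample_nearest(dem, config.pixel_size, shape).data

    names = config.class_names
    if not names:
        raise ValueError("no signatures provided")
    scores = np.empty((len(names),) + shape)
    for k, name in enumerate(names):
        sig = config.signatures[name]
        field_k = _smooth_field(rng, shape, config.patch_scale)
        suit = _elevation_suitability(elev, sig.elevation_range_m)
        scores[k] = field_k + 2.0 * np.clip(suit, -2.0, 1.0)

    # proportion balancing toward equal shares (deterministic)
    bias = np.zeros(len(names))
    target = 1.0 / len(names)
    for _ in range(8):
        labels = np.argmax(scores + bias[:, None, None], axis=0)
        props = np.bincount(labels.ravel(), minlength=len(names)) / labels.size
        bias += 0.35 * np.log(target / np.maximum(props, 1e-4))
    labels = np.argmax(scores + bias[:, None, None], axis=0)

    # map positions in `names` back to catalogue indices
    cat_idx = np.array([config.catalogue.index(n) for n in names])
    truth = cat_idx[labels]
    return RasterGrid(truth.astype(np.int16), config.pixel_size, (0.0, 0.0), nodata=-1)


def _cloud_mask(rng: np.random.Generator, shape: tuple[int, int],
                fraction: float, scale: float) -> np.ndarray:
    if fraction <= 0:
        return np.zeros(shape, dtype=bool)
    if fraction >= 1:
        return np.ones(shape, dtype=bool)
    f = _smooth_field(rng, shape, scale)
    thresh = np.quantile(f, 1.0 - fraction)
    return f >= thresh


def generate_optical_series(truth: RasterGrid, config: SceneConfig) -> tuple[ImageTimeSeries, list[np.ndarray]]:
    """Optical reflectance time series with seasonality, noise and clouds.

    Per date: reflectance = class mean + seasonal sinusoid + Gaussian
    noise, clipped to [0, 1]. A contiguous cloud blob covering about
    ``cloud_fraction`` of the scene brightens all bands and saturates
    the blue and cirrus-proxy layers. Returns the series plus the true
    per-date cloud masks.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    names = config.class_names
    present = set(np.unique(truth.data))
    missing = [config.catalogue.classes[i] for i in present
               if config.catalogue.classes[i] not in config.signatures]
    if missing:
        raise ValueError(f"truth contains classes without signatures: {missing}")

    idx_of = {config.catalogue.index(n): k for k, n in enumerate(names)}
    lookup = np.zeros(max(idx_of) + 1, dtype=int)
    for ci, k in idx_of.items():
        lookup[ci] = k
    klabels = lookup[truth.data]

    means = np.array([config.signatures[n].optical_mean for n in names])
    sds = np.array([config.signatures[n].optical_sd for n in names])
    amps = np.array([config.signatures[n].seasonal_amplitude for n in names])

    stacks, cloud_masks = [], []
    n_dates = config.n_optical_dates
    for t in range(n_dates):
        season = np.sin(2.0 * np.pi * t / max(n_dates, 1))
        bands: dict[str, np.ndarray] = {}
        for b, bname in enumerate(OPTICAL_BANDS):
            base = means[klabels, b] + amps[klabels, b] * season
            noise = rng.standard_normal(truth.shape) * sds[klabels, b]
            bands[bname] = np.clip(base + noise, 0.0, 1.0)
        bands["Aerosol"] = np.clip(
            0.05 + 0.01 * rng.standard_normal(truth.shape), 0.0, 1.0)
        bands["Cirrus"] = np.clip(
            0.005 + 0.003 * rng.standard_normal(truth.shape), 0.0, 1.0)

        cloud = _cloud_mask(rng, truth.shape, config.cloud_fraction,
                            config.patch_scale * 1.5)
        if cloud.any():
            for bname in OPTICAL_BANDS:
                bands[bname] = np.where(
                    cloud, np.clip(bands[bname] + 0.35, 0.0, 1.0), bands[bname])
            bands["Blue"] = np.where(cloud, np.maximum(bands["Blue"], 0.5), bands["Blue"])
            bands["Aerosol"] = np.where(cloud, 0.45, bands["Aerosol"])
            bands["Cirrus"] = np.where(cloud, 0.3, bands["Cirrus"])
        cloud_masks.append(cloud)
        stacks.append(SceneStack(bands, config.pixel_size, (0.0, 0.0),
                                 mask=None, timestamp=float(t)))
    return ImageTimeSeries(stacks), cloud_masks


def generate_sar_series(truth: RasterGrid, config: SceneConfig) -> ImageTimeSeries:
    """Radar backscatter series with multiplicative Gamma speckle.

    Per date and polarisation, linear-power backscatter is the class
    mean power times Gamma(looks, 1/looks) speckle (unit mean), stored
    in dB. Radar sees through clouds, so no masking is applied.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    names = config.class_names
    idx_of = {config.catalogue.index(n): k for k, n in enumerate(names)}
    lookup = np.zeros(max(idx_of) + 1, dtype=int)
    for ci, k in idx_of.items():
        lookup[ci] = k
    klabels = lookup[truth.data]

    mean_db = np.array([config.signatures[n].sar_mean_db for n in names])  # (k, 2)
    looks = np.array([config.signatures[n].speckle_looks for n in names])
    if (looks < 1).any():
        raise ValueError("speckle looks must be >= 1")
    mean_power = 10.0 ** (mean_db / 10.0)
    px_looks = looks[klabels].astype(float)

    stacks = []
    for t in range(config.n_radar_dates):
        bands = {}
        for p, pol in enumerate(("VV", "VH")):
            speckle = rng.gamma(shape=px_looks, scale=1.0 / px_looks)
            power = mean_power[klabels, p] * speckle
            bands[pol] = 10.0 * np.log10(np.maximum(power, 1e-12))
        stacks.append(SceneStack(bands, config.pixel_size, (0.0, 0.0),
                                 mask=None, timestamp=float(t)))
    return ImageTimeSeries(stacks)


def _uniform_blocks(labels: np.ndarray, cls_idx: int, size: int) -> np.ndarray:
    """Top-left corners (r, c) of size x size blocks entirely of cls_idx."""
    is_cls = labels == cls_idx
    if size == 1:
        rr, cc = np.nonzero(is_cls)
        return np.stack([rr, cc], axis=1)
    from numpy.lib.stride_tricks import sliding_window_view

    windows = sliding_window_view(is_cls, (size, size))
    full = windows.all(axis=(-2, -1))
    rr, cc = np.nonzero(full)
    return np.stack([rr, cc], axis=1)


def sample_reference(
    truth: RasterGrid,
    n_polygons_per_class: int = 4,
    n_points_per_class: int = 50,
    seed: int = 0,
    polygon_size: int = 6,
    catalogue: ClassCatalogue | None = None,
) -> ReferenceSet:
    """Sample training rectangles and stratified-random test points.

    Training polygons are axis-aligned rectangles of ``polygon_size``
    pixels a side placed fully inside single-class patches (falling back
    to smaller rectangles for fragmented classes); test points are drawn
    per class from pixels outside all training polygons. Labels come
    from the truth raster.
    """
    catalogue = catalogue if catalogue is not None else default_catalogue()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    labels = np.asarray(truth.data)
    ps = truth.pixel_size
    x0, y0 = truth.origin

    present = set(np.unique(labels))
    training: list[tuple[object, str]] = []
    testing: list[tuple[object, str]] = []
    taken = np.zeros(labels.shape, dtype=bool)  # pixels inside training polygons

    for name in catalogue.classes:
        ci = catalogue.index(name)
        if ci not in present:
            raise ValueError(f"class {name!r} absent from the truth map")

        placed = 0
        for size in range(polygon_size, 0, -1):
            if placed >= n_polygons_per_class:
                break
            corners = _uniform_blocks(labels, ci, size)
            if len(corners) == 0:
                continue
            order = rng.permutation(len(corners))
            for j in order:
                if placed >= n_polygons_per_class:
                    break
                r, c = corners[j]
                if taken[r:r + size, c:c + size].any():
                    continue
                taken[r:r + size, c:c + size] = True
                poly = box(x0 + c * ps, y0 - (r + size) * ps,
                           x0 + (c + size) * ps, y0 - r * ps)
                training.append((poly, name))
                placed += 1
        if placed == 0:
            raise ValueError(f"could not place a training polygon for {name!r}")

    for name in catalogue.classes:
        ci = catalogue.index(name)
        rr, cc = np.nonzero((labels == ci) & ~taken)
        if n_points_per_class == 0:
            continue
        if len(rr) == 0:
            raise ValueError(f"no free pixels for test points of {name!r}")
        n_take = min(n_points_per_class, len(rr))
        pick = rng.choice(len(rr), size=n_take, replace=False)
        for j in pick:
            x = x0 + (cc[j] + 0.5) * ps
            y = y0 - (rr[j] + 0.5) * ps
            testing.append((Point(x, y), name))

    return ReferenceSet(training=training, testing=testing)


def generate_scene(config: SceneConfig | None = None,
                   n_polygons_per_class: int = 4,
                   n_points_per_class: int = 50) -> LabeledScene:
    """Generate a full labelled scene (truth, imagery, DEM, reference)."""
    config = config if config is not None else SceneConfig()
    dem = generate_dem(config)
    truth = generate_class_map(config, dem)
    optical, cloud_truth = generate_optical_series(truth, config)
    radar = generate_sar_series(truth, config)
    reference = sample_reference(truth, n_polygons_per_class, n_points_per_class,
                                 seed=config.seed, catalogue=config.catalogue)
    return LabeledScene(truth, optical, radar, dem, reference, cloud_truth, config)
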