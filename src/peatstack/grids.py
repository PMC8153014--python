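"""Core raster containers.

All rasters are axis-aligned, north-up, row-major 2-D arrays in a single
shared coordinate reference system. Coordinates follow the pixel-centre
convention: the centre of pixel (row, col) sits at

    x = origin_x + (col + 0.5) * pixel_size
    y = origin_y - (row + 0.5) * pixel_size

with the origin at the top-left corner of the top-left pixel. Nodata is
represented as NaN in floating-point rasters and as a sentinel value
(default -1) in categorical ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

Origin = tuple[float, float]


@dataclass
class RasterGrid:
    """A single georeferenced 2-D value grid."""

    data: np.ndarray
    pixel_size: float
    origin: Origin = (0.0, 0.0)
    nodata: float = float("nan")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("RasterGrid data must be 2-D")
        if not self.pixel_size > 0:
            raise ValueError("pixel size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def same_grid(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.pixel_size, other.pixel_size)
            and np.allclose(self.origin, other.origin)
        )

    def pixel_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) world coordinates of every pixel centre, each 2-D."""
        rows, cols = self.shape
        x = self.origin[0] + (np.arange(cols) + 0.5) * self.pixel_size
        y = self.origin[1] - (np.arange(rows) + 0.5) * self.pixel_size
        return np.meshgrid(x, y)

    def world_to_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the pixel containing each world point (may be out of range)."""
        col = np.floor((np.asarray(x) - self.origin[0]) / self.pixel_size).astype(int)
        row = np.floor((self.origin[1] - np.asarray(y)) / self.pixel_size).astype(int)
        return row, col

    def copy(self) -> "RasterGrid":
        return RasterGrid(self.data.copy(), self.pixel_size, self.origin, self.nodata)


@dataclass
class SceneStack:
    """Named co-registered bands on one grid at one timestamp.

    ``mask`` is the validity mask (True = usable pixel); None means all
    pixels are valid.
    """

    bands: dict[str, np.ndarray]
    pixel_size: float
    origin: Origin = (0.0, 0.0)
    mask: np.ndarray | None = None
    timestamp: float | None = None

    def __post_init__(self) -> None:
        shapes = {name: np.asarray(b).shape for name, b in self.bands.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"bands disagree on shape: {shapes}")
        self.bands = {k: np.asarray(v) for k, v in self.bands.items()}
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.shape:
                raise ValueError("mask shape does not match bands")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape

    @property
    def band_names(self) -> tuple[str, ...]:
        return tuple(self.bands)

    def valid_mask(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.shape, dtype=bool)
        return self.mask

    def band(self, name: str) -> np.ndarray:
        if name not in self.bands:
            raise KeyError(
                f"band {name!r} absent; available: {sorted(self.bands)}"
            )
        return self.bands[name]

    def with_mask(self, mask: np.ndarray) -> "SceneStack":
        return SceneStack(dict(self.bands), self.pixel_size, self.origin,
                          np.asarray(mask, dtype=bool), self.timestamp)

    def grid(self) -> RasterGrid:
        return RasterGrid(next(iter(self.bands.values())), self.pixel_size, self.origin)


class ImageTimeSeries:
    """Time-ordered sequence of SceneStacks sharing band names and grid."""

    def __init__(self, stacks: Sequence[SceneStack]):
        stacks = list(stacks)
        if not stacks:
            raise ValueError("empty image time series")
        names = stacks[0].band_names
        shape = stacks[0].shape
        for s in stacks[1:]:
            if s.band_names != names:
                raise ValueError("stacks disagree on band names")
            if s.shape != shape or not np.isclose(s.pixel_size, stacks[0].pixel_size):
                raise ValueError("stacks disagree on grid")
        times = [s.timestamp for s in stacks]
        if all(t is not None for t in times):
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValueError("timestamps must be strictly increasing")
        self.stacks = stacks

    @property
    def band_names(self) -> tuple[str, ...]:
        return self.stacks[0].band_names

    @property
    def shape(self) -> tuple[int, int]:
        return self.stacks[0].shape

    @property
    def pixel_size(self) -> float:
        return self.stacks[0].pixel_size

    @property
    def origin(self) -> Origin:
        return self.stacks[0].origin

    def __len__(self) -> int:
        return len(self.stacks)

    def __iter__(self) -> Iterator[SceneStack]:
        return iter(self.stacks)

    def __getitem__(self, i: int) -> SceneStack:
        return self.stacks[i]

    def band_cube(self, name: str) -> np.ndarray:
        """(time, rows, cols) array of one band with invalid pixels as NaN."""
        cube = np.stack([s.band(name).astype(float) for s in self.stacks])
        for t, s in enumerate(self.stacks):
            if s.mask is not None:
                cube[t][~s.mask] = np.nan
        return cube


#: The six dataset-combination tags.
COMBINATION_TAGS: tuple[str, ...] = ("S2", "S2+", "S1", "S1+", "S2+S1+", "S2+S1+DEM")


@dataclass
class FeatureStack:
    """Named derived feature layers on the analysis grid.

    ``tag`` records which dataset combination the stack represents;
    ``provenance`` carries a free-text note per feature (source bands,
    parameters).
    """

    features: dict[str, np.ndarray]
    pixel_size: float
    origin: Origin = (0.0, 0.0)
    tag: str | None = None
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tag is not None and self.tag not in COMBINATION_TAGS:
            raise ValueError(f"unknown combination tag {self.tag!r}")
        shapes = {k: np.asarray(v).shape for k, v in self.features.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"feature layers disagree on shape: {shapes}")
        self.features = {k: np.asarray(v, dtype=float) for k, v in self.features.items()}

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.features)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.features.values())).shape

    def layer(self, name: str) -> np.ndarray:
        if name not in self.features:
            raise KeyError(f"feature {name!r} absent; available: {sorted(self.features)}")
        return self.features[name]

    def as_array(self, order: Sequence[str] | None = None) -> np.ndarray:
        """(rows*cols, n_features) matrix in the given (or native) order."""
        names = list(order) if order is not None else list(self.names)
        return np.stack([self.layer(n).ravel() for n in names], axis=1)

    def subset(self, names: Sequence[str]) -> "FeatureStack":
        return FeatureStack(
            {n: self.layer(n) for n in names},
            self.pixel_size,
            self.origin,
            self.tag,
            {n: self.provenance.get(n, "") for n in names},
        )

    def __len__(self) -> int:
        return len(self.features)
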