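"""Raster and vector readers/writers and YAML configuration.

Rasters are stored as multi-band TIFF files whose ImageDescription tag
carries a JSON header with band names, pixel size (m), origin and the
nodata sentinel; a TIFF without that georeferencing header is rejected.
Reference data are GeoJSON feature collections: polygon features form
the training set, point features the testing set, and every feature must
carry a "class" property naming a catalogue class.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import tifffile
import yaml
from shapely.geometry import mapping, shape

from peatstack.catalogue import ClassCatalogue, default_catalogue
from peatstack.grids import RasterGrid, SceneStack
from peatstack.synthetic import ReferenceSet

log = logging.getLogger(__name__)

_HEADER_KEY = "peatstack"


def write_raster(path: str | Path, obj: SceneStack | RasterGrid) -> None:
    """Write a stack or single grid as a described multi-band TIFF."""
    path = Path(path)
    if isinstance(obj, RasterGrid):
        data = np.asarray(obj.data)[None]
        names = ["layer"]
        pixel_size, origin = obj.pixel_size, obj.origin
        nodata = obj.nodata
        mask = None
    else:
        names = list(obj.band_names)
        data = np.stack([obj.bands[n] for n in names])
        pixel_size, origin = obj.pixel_size, obj.origin
        nodata = float("nan")
        mask = obj.mask
    header = {
        _HEADER_KEY: {
            "bands": names,
            "pixel_size": pixel_size,
            "origin": list(origin),
            "nodata": "nan" if (isinstance(nodata, float) and np.isnan(nodata)) else nodata,
            "has_mask": mask is not None,
        }
    }
    if mask is not None:
        data = np.concatenate([data, mask[None].astype(data.dtype)])
    tifffile.imwrite(path, data, description=json.dumps(header),
                     photometric="minisblack")


def read_raster(path: str | Path) -> SceneStack:
    """Read a described TIFF back into a SceneStack.

    Errors on missing files, non-TIFF input and TIFFs without the
    georeferencing header. A header without a nodata entry defaults the
    sentinel to NaN (logged).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such raster: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description
    except Exception as exc:
        raise IOError(f"unreadable raster format: {path}") from exc
    try:
        header = json.loads(desc)[_HEADER_KEY]
    except Exception:
        raise IOError(f"raster lacks georeferencing header: {path}") from None

    if data.ndim == 2:
        data = data[None]
    names = header["bands"]
    if "nodata" not in header or header["nodata"] is None:
        log.info("%s: nodata not tagged, defaulting to NaN", path)
    mask = None
    if header.get("has_mask"):
        mask = data[-1].astype(bool)
        data = data[:-1]
    bands = {n: data[i] for i, n in enumerate(names)}
    return SceneStack(bands, float(header["pixel_size"]),
                      tuple(header["origin"]), mask)


def read_grid(path: str | Path) -> RasterGrid:
    """Read a single-band raster as a RasterGrid."""
    stack = read_raster(path)
    name = stack.band_names[0]
    return RasterGrid(stack.band(name), stack.pixel_size, stack.origin)


def write_reference(path: str | Path, reference: ReferenceSet) -> None:
    """Write training polygons and test points as GeoJSON."""
    feats = []
    for geom, cls in list(reference.training) + list(reference.testing):
        feats.append({
            "type": "Feature",
            "geometry": mapping(geom),
            "properties": {"class": cls},
        })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": feats}))


def read_reference(path: str | Path,
                   catalogue: ClassCatalogue | None = None) -> ReferenceSet:
    """Read GeoJSON reference data: polygons train, points test.

    Unknown class names, missing class properties and geometry types
    other than Polygon/Point are errors.
    """
    catalogue = catalogue if catalogue is not None else default_catalogue()
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such reference file: {path}")
    try:
        doc = json.loads(path.read_text())
        features = doc["features"]
    except Exception as exc:
        raise IOError(f"unreadable reference file: {path}") from exc
    if not features:
        raise ValueError(f"reference file holds no features: {path}")

    unknown: set[str] = set()
    training, testing = [], []
    for feat in features:
        props = feat.get("properties") or {}
        if "class" not in props:
            raise ValueError("reference feature without a 'class' property")
        cls = props["class"]
        if cls not in catalogue.classes:
            unknown.add(cls)
            continue
        geom = shape(feat["geometry"])
        if geom.geom_type == "Polygon":
            training.append((geom, cls))
        elif geom.geom_type == "Point":
            testing.append((geom, cls))
        else:
            raise ValueError(
                f"unsupported geometry type {geom.geom_type!r} (want Polygon or Point)")
    if unknown:
        raise ValueError(f"unknown land-cover classes in reference data: {sorted(unknown)}")
    return ReferenceSet(training, testing)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise ValueError(f"expected a mapping in {path}")
    return out


def dump_yaml(path: str | Path, obj: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
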