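"""End-to-end pipeline: simulate -> composite -> features -> select ->
classify -> filter -> evaluate -> compare, with a deterministic run
manifest.

The pipeline reproduces the six-combination comparative experiment on a
synthetic scene: each dataset combination is assembled, optionally
reduced by RFE, classified with the random forest, majority-filtered and
scored against the shared test points; combinations are then compared
pairwise with McNemar tests and a UA/PA improvement table against the
richest combination.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from peatstack import __version__
from peatstack.catalogue import default_catalogue
from peatstack.classify import majority_filter, predict_map, train_rf
from peatstack.compositing import (CompositeSpec, mask_clouds,
                                   percentile_range_composite)
from peatstack.evaluate import (confusion, discordant_counts,
                                improvement_analysis, area_report, mcnemar)
from peatstack.features import assemble_combination
from peatstack.grids import COMBINATION_TAGS
from peatstack.io import write_raster, write_reference
from peatstack.selection import (extract_training_pixels, rfe_select,
                                 standardize)
from peatstack.synthetic import SceneConfig, generate_scene

log = logging.getLogger(__name__)

_SCENE_KEYS = {"rows", "cols", "pixel_size", "dem_pixel_size",
               "n_optical_dates", "n_radar_dates", "cloud_fraction",
               "patch_scale"}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    scene: dict = field(default_factory=dict)
    combinations: list[str] = field(default_factory=lambda: list(COMBINATION_TAGS))
    p_lo: float = 40.0
    p_hi: float = 60.0
    cloud_threshold: float = 0.5
    min_valid: int = 1
    analysis_pixel_size: float = 20.0
    ntree: int = 100
    mtry: int = 2
    run_rfe: bool = True
    n_polygons_per_class: int = 4
    n_points_per_class: int = 50
    seed: int = 0
    report_precision: int = 2

    def __post_init__(self) -> None:
        unknown = set(self.scene) - _SCENE_KEYS
        if unknown:
            raise ValueError(f"unknown scene keys: {sorted(unknown)}")
        bad = [t for t in self.combinations if t not in COMBINATION_TAGS]
        if bad:
            raise ValueError(f"unknown combination tags: {bad}")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def scene_config(self) -> SceneConfig:
        return SceneConfig(seed=self.seed, **self.scene)


@dataclass
class RunManifest:
    """Checksums, seeds and timings of one pipeline run."""

    tool_version: str
    config_hash: str
    seeds: dict
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, seconds: float, outputs: dict[str, str]) -> None:
        self.stages[stage] = {"seconds": round(seconds, 3), "outputs": outputs}

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> RunManifest:
    """Execute the full experiment and write all reports and the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalogue = default_catalogue()
    manifest = RunManifest(__version__, _config_hash(config),
                           seeds={"scene": config.seed, "forest": config.seed})

    def _stage(name):
        log.info("stage: %s", name)
        return time.perf_counter()

    # simulate
    t0 = _stage("simulate")
    scene = generate_scene(config.scene_config(),
                           config.n_polygons_per_class,
                           config.n_points_per_class)
    truth_path = outdir / "truth.tif"
    write_raster(truth_path, scene.truth)
    ref_path = outdir / "reference.geojson"
    write_reference(ref_path, scene.reference)
    manifest.record("simulate", time.perf_counter() - t0, {
        "truth.tif": _sha256(truth_path),
        "reference.geojson": _sha256(ref_path),
    })

    # composite
    t0 = _stage("composite")
    spec = CompositeSpec(config.p_lo, config.p_hi, min_valid=config.min_valid)
    optical_masked = mask_clouds(scene.optical_series, config.cloud_threshold)
    n_masked = int(sum((~s.valid_mask()).sum() for s in optical_masked))
    log.info("pixels masked as cloud: %d", n_masked)
    optical_comp = percentile_range_composite(optical_masked, spec)
    radar_comp = percentile_range_composite(scene.radar_series, spec)
    opt_path = outdir / "optical_composite.tif"
    rad_path = outdir / "radar_composite.tif"
    write_raster(opt_path, optical_comp)
    write_raster(rad_path, radar_comp)
    manifest.record("composite", time.perf_counter() - t0, {
        "optical_composite.tif": _sha256(opt_path),
        "radar_composite.tif": _sha256(rad_path),
    })

    # per-combination classification
    reports = {}
    maps = {}
    for tag in config.combinations:
        t0 = _stage(f"classify[{tag}]")
        feats = assemble_combination(
            tag, optical=optical_comp, radar=radar_comp,
            radar_series=scene.radar_series, dem=scene.dem,
            pixel_size=config.analysis_pixel_size)
        table = extract_training_pixels(feats, scene.reference)
        table = standardize(table)

        outputs = {}
        if config.run_rfe and table.n_features >= 2:
            sel = rfe_select(table, {"ntree": config.ntree, "mtry": config.mtry},
                             seed=config.seed)
            log.info("%s: RFE kept %d of %d features", tag, sel.optimal_size,
                     table.n_features)
            sel_path = outdir / f"selection_{tag.replace('+', 'p')}.json"
            sel_path.write_text(json.dumps(sel.to_dict(), indent=1))
            outputs[sel_path.name] = _sha256(sel_path)
            table = table.subset(sel.selected)
            feats = feats.subset(sel.selected)

        model = train_rf(table, config.ntree, config.mtry, seed=config.seed)
        cmap = majority_filter(predict_map(model, feats, catalogue))
        report = confusion(cmap, scene.reference.testing)
        maps[tag], reports[tag] = cmap, report

        safe = tag.replace("+", "p")
        map_path = outdir / f"map_{safe}.tif"
        from peatstack.grids import RasterGrid
        write_raster(map_path, RasterGrid(cmap.data, cmap.pixel_size,
                                          cmap.origin, nodata=-1))
        acc_path = outdir / f"accuracy_{safe}.json"
        acc_path.write_text(json.dumps({
            "tag": tag,
            "oa": round(report.oa, config.report_precision),
            "ua": {k: None if np.isnan(v) else round(v, config.report_precision)
                   for k, v in report.ua.items()},
            "pa": {k: None if np.isnan(v) else round(v, config.report_precision)
                   for k, v in report.pa.items()},
            "f": {k: None if np.isnan(v) else round(v, config.report_precision)
                  for k, v in report.f.items()},
        }, indent=1))
        outputs[map_path.name] = _sha256(map_path)
        outputs[acc_path.name] = _sha256(acc_path)
        manifest.record(f"classify[{tag}]", time.perf_counter() - t0, outputs)

    # comparison
    t0 = _stage("compare")
    ref_tag = "S2+S1+DEM" if "S2+S1+DEM" in reports else config.combinations[0]
    rows = []
    tags = list(reports)
    for i, a in enumerate(tags):
        for b in tags[i + 1:]:
            f12, f21 = discordant_counts(maps[a], maps[b], scene.reference.testing)
            if f12 + f21 > 0:
                statistic, p = mcnemar(f12, f21)
            else:
                statistic, p = float("nan"), float("nan")
            rows.append({"dataset_a": a, "dataset_b": b, "f12": f12, "f21": f21,
                         "statistic": statistic, "p": p})
    pairs = pd.DataFrame(rows)
    others = {t: reports[t].ua_pa_frame() for t in tags if t != ref_tag}
    comparison = None
    if others:
        comparison = improvement_analysis(reports[ref_tag].ua_pa_frame(), others,
                                          mcnemar_pairs=pairs)
    cmp_path = outdir / "comparison.json"
    cmp_path.write_text(json.dumps({
        "reference": ref_tag,
        "mcnemar": rows,
        "improvement": None if comparison is None else {
            "positive": comparison.n_positive,
            "negative": comparison.n_negative,
            "zero": comparison.n_zero,
        },
        "oa": {t: round(reports[t].oa, config.report_precision) for t in tags},
    }, indent=1, default=float))
    area = area_report(maps[ref_tag], catalogue)
    area_path = outdir / "areas.csv"
    area.per_class.round(config.report_precision).to_csv(area_path)
    manifest.record("compare", time.perf_counter() - t0, {
        "comparison.json": _sha256(cmp_path),
        "areas.csv": _sha256(area_path),
    })

    man_path = outdir / "manifest.json"
    man_path.write_text(json.dumps(manifest.to_dict(), indent=1))
    return manifest
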