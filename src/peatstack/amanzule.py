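"""Published reference tables for the Greater Amanzule (Ghana) peatland
classification.

Small CSVs shipped with the package hold the published per-class
accuracies, map-comparison statistics, reference-data counts and class
areas of the Greater Amanzule land-cover classification. They serve as
inputs to the accuracy / comparison / area accounting layer — e.g. to
recompute F-scores from UA/PA, recover McNemar p-values from the
chi-squared statistics, or aggregate class areas into general-class
totals.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from peatstack.grids import COMBINATION_TAGS


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("peatstack").joinpath("data", "amanzule", name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def ua_pa_tables() -> dict[str, pd.DataFrame]:
    """Per-dataset class-indexed frames of UA and PA (percent)."""
    raw = _read("ua_pa.csv")
    out = {}
    for tag in COMBINATION_TAGS:
        sub = raw[raw["dataset"] == tag].set_index("class")[["UA", "PA"]]
        out[tag] = sub
    return out


def class_areas_ha() -> dict[str, float]:
    """Published per-class areas (ha) of the final classification."""
    raw = _read("areas.csv")
    return dict(zip(raw["class"], raw["area_ha"]))


def reference_counts() -> pd.DataFrame:
    """Training-pixel and test-point counts per class."""
    return _read("reference_counts.csv").set_index("class")


def mcnemar_statistics() -> pd.DataFrame:
    """Published pairwise McNemar chi-squared statistics and p-values."""
    return _read("mcnemar.csv")


def overall_accuracies() -> pd.Series:
    """Published overall accuracy (percent) per dataset combination."""
    raw = _read("overall_accuracy.csv")
    return raw.set_index("dataset")["OA"]
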