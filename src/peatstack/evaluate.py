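"""Thematic-map accuracy assessment, map comparison and area accounting.

Accuracy is summarised by a confusion matrix (reference classes by rows,
predictions by columns) with user's accuracy (UA, column-wise
correctness), producer's accuracy (PA, row-wise correctness), overall
accuracy (OA) and a per-class F-score, the harmonic mean of UA and PA:

    F = 2 * UA * PA / (UA + PA) / 100        (UA, PA in percent)

Pairs of maps over shared test points are compared with McNemar's
chi-squared test on the discordant counts f12 (correct in the first map
only) and f21 (correct in the second only):

    chi2 = (f12 - f21)^2 / (f12 + f21),  p from chi2 with 1 df,
    no continuity correction.

Areas follow from pixel counts: a 20 m pixel is 0.04 ha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from peatstack.catalogue import ClassCatalogue, default_catalogue
from peatstack.classify import NODATA_CLASS, ClassMap

log = logging.getLogger(__name__)


@dataclass
class AccuracyReport:
    """Confusion-matrix-derived accuracy statistics (UA/PA/OA in percent)."""

    matrix: pd.DataFrame            # rows = reference, cols = predicted
    ua: pd.Series                   # percent; NaN where undefined
    pa: pd.Series
    oa: float
    f: pd.Series                    # unitless in (0, 1]
    n_dropped: int = 0
    tag: str | None = None

    @property
    def n_points(self) -> int:
        return int(self.matrix.to_numpy().sum())

    def ua_pa_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"UA": self.ua, "PA": self.pa})


def f_score(ua: float, pa: float) -> float:
    """Harmonic mean of user's and producer's accuracy, on [0, 1].

    Inputs are percentages; undefined (NaN) when UA + PA = 0.
    """
    if np.isnan(ua) or np.isnan(pa) or ua + pa == 0:
        return float("nan")
    return 2.0 * ua * pa / (ua + pa) / 100.0


def accuracy_from_matrix(matrix: pd.DataFrame, n_dropped: int = 0,
                         tag: str | None = None) -> AccuracyReport:
    """UA/PA/OA/F from a counts matrix (reference rows, predicted columns)."""
    m = matrix.to_numpy(dtype=float)
    total = m.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(m)
    col_sums = m.sum(axis=0)
    row_sums = m.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ua = np.where(col_sums > 0, 100.0 * diag / col_sums, np.nan)
        pa = np.where(row_sums > 0, 100.0 * diag / row_sums, np.nan)
    oa = 100.0 * diag.sum() / total
    classes = list(matrix.index)
    ua_s = pd.Series(ua, index=classes, name="UA")
    pa_s = pd.Series(pa, index=classes, name="PA")
    f = pd.Series([f_score(u, p) for u, p in zip(ua, pa)], index=classes, name="F")
    return AccuracyReport(matrix, ua_s, pa_s, float(oa), f, n_dropped, tag)


def confusion(class_map: ClassMap, test_points) -> AccuracyReport:
    """Tally test points against the map.

    ``test_points`` is an iterable of (shapely Point, class name). Points
    falling on nodata pixels (or outside the map) are dropped with a
    logged count.
    """
    test_points = list(test_points)
    if not test_points:
        raise ValueError("empty test set")
    cat = class_map.catalogue
    xs = np.array([p.x for p, _ in test_points])
    ys = np.array([p.y for p, _ in test_points])
    ref = np.array([cat.index(c) for _, c in test_points])
    pred = class_map.sample(xs, ys)

    keep = pred != NODATA_CLASS
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("dropped %d test points on nodata pixels", n_dropped)
    if not keep.any():
        raise ValueError("all test points fall on nodata pixels")
    ref, pred = ref[keep], pred[keep]

    k = len(cat)
    m = np.zeros((k, k), dtype=int)
    np.add.at(m, (ref, pred), 1)
    matrix = pd.DataFrame(m, index=list(cat.classes), columns=list(cat.classes))
    return accuracy_from_matrix(matrix, n_dropped, class_map.tag)


def mcnemar(f12: int, f21: int) -> tuple[float, float]:
    """McNemar chi-squared statistic and p-value (1 df, no correction).

    Symmetric in (f12, f21); undefined when both counts are zero.
    """
    if f12 < 0 or f21 < 0:
        raise ValueError("discordant counts must be non-negative")
    n = f12 + f21
    if n == 0:
        raise ValueError("McNemar test undefined with no discordant samples")
    statistic = (f12 - f21) ** 2 / n
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p


def discordant_counts(map_a: ClassMap, map_b: ClassMap, test_points) -> tuple[int, int]:
    """(f12, f21) over shared test points where exactly one map is correct.

    Points nodata in either map are excluded.
    """
    test_points = list(test_points)
    cat = map_a.catalogue
    xs = np.array([p.x for p, _ in test_points])
    ys = np.array([p.y for p, _ in test_points])
    ref = np.array([cat.index(c) for _, c in test_points])
    pa = map_a.sample(xs, ys)
    pb = map_b.sample(xs, ys)
    ok = (pa != NODATA_CLASS) & (pb != NODATA_CLASS)
    a_correct = (pa == ref) & ok
    b_correct = (pb == ref) & ok
    f12 = int((a_correct & ~b_correct).sum())
    f21 = int((~a_correct & b_correct).sum())
    return f12, f21


@dataclass
class ComparisonReport:
    """Pairwise McNemar results and the UA/PA improvement table."""

    mcnemar_pairs: pd.DataFrame | None      # columns f12, f21, statistic, p
    differences: pd.DataFrame               # classes x (dataset, metric)
    n_positive: int = 0
    n_negative: int = 0
    n_zero: int = 0

    @property
    def n_cells(self) -> int:
        return self.n_positive + self.n_negative + self.n_zero

    def percentages(self) -> dict[str, float]:
        n = self.n_cells
        return {
            "positive": 100.0 * self.n_positive / n,
            "negative": 100.0 * self.n_negative / n,
            "zero": 100.0 * self.n_zero / n,
        }


def improvement_analysis(
    reference: pd.DataFrame,
    others: dict[str, pd.DataFrame],
    mcnemar_pairs: pd.DataFrame | None = None,
    atol: float = 1e-9,
) -> ComparisonReport:
    """Difference of the reference dataset's UA/PA against each other dataset.

    ``reference`` and each entry of ``others`` are class-indexed frames
    with UA and PA columns (percent). Each difference cell is
    reference - other; cells are counted as strictly positive, strictly
    negative or zero (|d| <= atol).
    """
    blocks = {}
    for name, frame in others.items():
        if list(frame.index) != list(reference.index):
            raise ValueError(f"class list of {name!r} differs from the reference")
        for metric in ("UA", "PA"):
            blocks[(name, metric)] = reference[metric] - frame[metric]
    diff = pd.DataFrame(blocks)
    vals = diff.to_numpy(dtype=float)
    n_zero = int((np.abs(vals) <= atol).sum())
    n_pos = int((vals > atol).sum())
    n_neg = int((vals < -atol).sum())
    return ComparisonReport(mcnemar_pairs, diff, n_pos, n_neg, n_zero)


@dataclass
class AreaReport:
    """Per-class and per-general-class area accounting."""

    per_class: pd.DataFrame     # columns: area_ha, percent (and pixels if known)
    per_general: pd.DataFrame   # columns: area_ha, percent
    total_area_ha: float
    pixel_area_ha: float | None = None


def aggregate_areas(
    class_areas_ha: dict[str, float],
    catalogue: ClassCatalogue | None = None,
    pixel_area_ha: float | None = None,
    pixel_counts: dict[str, int] | None = None,
) -> AreaReport:
    """Build an AreaReport from per-class areas in hectares."""
    catalogue = catalogue if catalogue is not None else default_catalogue()
    unknown = set(class_areas_ha) - set(catalogue.classes)
    if unknown:
        raise ValueError(f"areas for unknown classes: {sorted(unknown)}")
    classes = [c for c in catalogue.classes if c in class_areas_ha]
    areas = np.array([class_areas_ha[c] for c in classes], dtype=float)
    total = float(areas.sum())
    per_class = pd.DataFrame(
        {"area_ha": areas, "percent": 100.0 * areas / total}, index=classes
    )
    if pixel_counts is not None:
        per_class.insert(0, "pixels", [pixel_counts.get(c, 0) for c in classes])

    rows = {}
    for g in catalogue.general_classes():
        members = [c for c in catalogue.members(g) if c in class_areas_ha]
        if members:
            a = float(per_class.loc[members, "area_ha"].sum())
            rows[g] = {"area_ha": a, "percent": 100.0 * a / total}
    per_general = pd.DataFrame(rows).T
    return AreaReport(per_class, per_general, total, pixel_area_ha)


def area_report(class_map: ClassMap, catalogue: ClassCatalogue | None = None) -> AreaReport:
    """Area accounting of a class map (percentages over mapped pixels)."""
    catalogue = catalogue if catalogue is not None else class_map.catalogue
    pixel_area_ha = class_map.pixel_size**2 / 10_000.0
    data = class_map.data
    mapped = data != NODATA_CLASS
    if not mapped.any():
        raise ValueError("map holds no mapped pixels")
    counts = np.bincount(data[mapped].ravel(), minlength=len(catalogue))
    class_areas = {
        catalogue.classes[i]: counts[i] * pixel_area_ha
        for i in range(len(catalogue))
    }
    pixel_counts = {catalogue.classes[i]: int(counts[i]) for i in range(len(catalogue))}
    return aggregate_areas(class_areas, catalogue, pixel_area_ha, pixel_counts)
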