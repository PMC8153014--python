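"""Training-pixel extraction, standardisation and recursive feature
elimination (RFE) with stratified 2-fold cross-validation.

RFE repeatedly fits the random forest, drops the single feature with the
lowest overall Gini importance, and records the stratified 2-fold
cross-validated overall accuracy at every subset size. The returned
subset maximises the CV curve, with ties broken toward the smaller
(more parsimonious) subset. Fold assignment is stratified by class,
seeded, and held fixed along the whole elimination path so the curve
reflects feature content rather than fold noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from shapely import contains_xy
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from peatstack.grids import FeatureStack
from peatstack.synthetic import ReferenceSet

log = logging.getLogger(__name__)

#: Forest hyperparameters: number of trees and candidate features per split.
DEFAULT_FOREST_PARAMS = {"ntree": 100, "mtry": 2}


@dataclass
class TrainingTable:
    """Pixels-by-features sample matrix with class labels.

    ``means``/``scales`` hold the per-feature standardisation parameters
    (population statistics estimated on the training pixels only) so the
    same transform can later be applied to full rasters.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    tag: str | None = None
    means: np.ndarray | None = None
    scales: np.ndarray | None = None
    zero_variance: np.ndarray | None = None
    standardized: bool = False

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("sample matrix must be 2-D")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("rows of X and labels differ in number")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature count does not match names")
        if not np.isfinite(self.X).all():
            raise ValueError("non-finite entries in the sample matrix")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> dict[str, int]:
        vals, counts = np.unique(self.y, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def subset(self, names: list[str]) -> "TrainingTable":
        idx = [self.feature_names.index(n) for n in names]
        return TrainingTable(
            self.X[:, idx], self.y, list(names), self.tag,
            self.means[idx] if self.means is not None else None,
            self.scales[idx] if self.scales is not None else None,
            self.zero_variance[idx] if self.zero_variance is not None else None,
            self.standardized,
        )


def extract_training_pixels(
    features: FeatureStack, reference: ReferenceSet
) -> TrainingTable:
    """One row per pixel whose centre lies inside a training polygon.

    The polygon's class labels the row; rows with any nodata feature are
    dropped (count logged).
    """
    names = list(features.names)
    rows, cols = features.shape
    ps = features.pixel_size
    x0, y0 = features.origin

    xs = x0 + (np.arange(cols) + 0.5) * ps
    ys = y0 - (np.arange(rows) + 0.5) * ps
    XX, YY = np.meshgrid(xs, ys)
    flat_x, flat_y = XX.ravel(), YY.ravel()

    mat = features.as_array(names)

    X_rows, y_rows = [], []
    any_inside = False
    for poly, cls in reference.training:
        minx, miny, maxx, maxy = poly.bounds
        cand = ((flat_x >= minx) & (flat_x <= maxx)
                & (flat_y >= miny) & (flat_y <= maxy))
        if not cand.any():
            continue
        inside = contains_xy(poly, flat_x[cand], flat_y[cand])
        if not inside.any():
            continue
        any_inside = True
        sel = np.nonzero(cand)[0][inside]
        X_rows.append(mat[sel])
        y_rows.append(np.full(len(sel), cls, dtype=object))

    if not any_inside:
        raise ValueError("no training polygon covers any pixel centre")

    X = np.concatenate(X_rows)
    y = np.concatenate(y_rows)
    finite = np.isfinite(X).all(axis=1)
    dropped = int((~finite).sum())
    if dropped:
        log.info("dropped %d training pixels with nodata features", dropped)
    X, y = X[finite], y[finite]
    if len(X) == 0:
        raise ValueError("all extracted training pixels carry nodata features")
    return TrainingTable(X, y, names, tag=features.tag)


def standardize(table: TrainingTable) -> TrainingTable:
    """Centre each feature to mean 0 and scale to unit population variance.

    Zero-variance columns are scaled by 1 and flagged. The estimated
    parameters are stored on the table for later application to rasters.
    """
    means = table.X.mean(axis=0)
    sds = table.X.std(axis=0)  # population sd
    zero_var = sds == 0
    scales = np.where(zero_var, 1.0, sds)
    Xs = (table.X - means) / scales
    return TrainingTable(Xs, table.y, list(table.feature_names), table.tag,
                         means, scales, zero_var, standardized=True)


@dataclass
class SelectionResult:
    """Outcome of the RFE run: the CV curve and the chosen subset."""

    cv_scores: dict[int, float]          # subset size -> mean CV accuracy
    optimal_size: int
    selected: list[str]
    elimination_order: list[str]         # first eliminated first
    seed: int

    def to_dict(self) -> dict:
        return {
            "cv_scores": {str(k): v for k, v in self.cv_scores.items()},
            "optimal_size": self.optimal_size,
            "selected": self.selected,
            "elimination_order": self.elimination_order,
            "seed": self.seed,
        }


def _make_forest(forest_params: dict, seed: int, n_features: int) -> RandomForestClassifier:
    ntree = forest_params.get("ntree", 100)
    mtry = forest_params.get("mtry", 2)
    if ntree < 1:
        raise ValueError("ntree must be >= 1")
    if not 1 <= mtry <= n_features:
        raise ValueError(f"mtry={mtry} outside [1, {n_features}]")
    return RandomForestClassifier(
        n_estimators=ntree, max_features=mtry, criterion="gini",
        random_state=seed, n_jobs=1,
    )


def _cv_accuracy(X: np.ndarray, y: np.ndarray, folds, forest_params: dict,
                 seed: int) -> float:
    accs = []
    for train_idx, test_idx in folds:
        clf = _make_forest(forest_params, seed, X.shape[1])
        clf.fit(X[train_idx], y[train_idx])
        accs.append(float(np.mean(clf.predict(X[test_idx]) == y[test_idx])))
    return float(np.mean(accs))


def rfe_select(
    table: TrainingTable,
    forest_params: dict | None = None,
    seed: int = 0,
) -> SelectionResult:
    """Recursive feature elimination, one feature per step.

    At each subset size the stratified 2-fold CV overall accuracy is
    recorded, then the feature with the lowest overall Gini importance
    (first such feature on ties) is dropped. The optimal size maximises
    the curve; ties go to the smaller subset.
    """
    forest_params = forest_params if forest_params is not None else dict(DEFAULT_FOREST_PARAMS)
    if table.n_features < 2:
        raise ValueError("need at least 2 features for elimination")
    counts = table.class_counts()
    thin = [c for c, n in counts.items() if n < 2]
    if thin:
        raise ValueError(f"classes with fewer than 2 samples: {thin}")

    skf = StratifiedKFold(n_splits=2, shuffle=True, random_state=seed)
    folds = list(skf.split(table.X, table.y))

    current = list(table.feature_names)
    name_to_col = {n: i for i, n in enumerate(table.feature_names)}
    cv_scores: dict[int, float] = {}
    eliminated: list[str] = []

    while current:
        cols = [name_to_col[n] for n in current]
        X = table.X[:, cols]
        mtry = min(forest_params.get("mtry", 2), len(current))
        params = dict(forest_params, mtry=mtry)
        cv_scores[len(current)] = _cv_accuracy(X, table.y, folds, params, seed)
        if len(current) == 1:
            break
        clf = _make_forest(params, seed, len(current))
        clf.fit(X, table.y)
        drop = current[int(np.argmin(clf.feature_importances_))]
        eliminated.append(drop)
        current.remove(drop)

    best = min(
        (size for size in cv_scores
         if cv_scores[size] == max(cv_scores.values()))
    )
    # reconstruct the surviving subset at the optimal size, in input order
    removed_before = set(eliminated[: table.n_features - best])
    selected = [n for n in table.feature_names if n not in removed_before]
    return SelectionResult(cv_scores, best, selected, eliminated, seed)
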