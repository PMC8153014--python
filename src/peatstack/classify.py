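"""Random-forest classification, raster prediction, majority filtering and
feature-importance decomposition.

The classifier is a bagged ensemble of Gini-split decision trees with
ntree = 100 trees and mtry = 2 candidate features per split. Overall
feature importance is the normalised mean decrease in Gini impurity; the
per-class importance of a feature is the product of its overall
importance and the absolute standardised mean of that feature over the
class's training pixels, which attributes each feature's impurity
reduction to the classes whose signatures deviate most along it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from peatstack.catalogue import ClassCatalogue, default_catalogue
from peatstack.grids import FeatureStack
from peatstack.selection import TrainingTable, _make_forest

NODATA_CLASS = -1


@dataclass
class TrainedClassifier:
    """A fitted forest plus everything needed to apply it to rasters."""

    model: RandomForestClassifier
    feature_names: list[str]
    classes: list[str]
    params: dict
    seed: int
    importances: np.ndarray
    means: np.ndarray | None = None
    scales: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.importances < 0).any():
            raise ValueError("importances must be non-negative")
        total = self.importances.sum()
        if total > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError("importances must sum to 1")


def train_rf(
    table: TrainingTable,
    ntree: int = 100,
    mtry: int = 2,
    seed: int = 0,
) -> TrainedClassifier:
    """Fit the random forest on a standardised training table."""
    if not table.standardized:
        raise ValueError("training table must be standardised first")
    clf = _make_forest({"ntree": ntree, "mtry": mtry}, seed, table.n_features)
    clf.fit(table.X, table.y)
    imp = clf.feature_importances_
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return TrainedClassifier(
        model=clf,
        feature_names=list(table.feature_names),
        classes=[str(c) for c in clf.classes_],
        params={"ntree": ntree, "mtry": mtry},
        seed=seed,
        importances=imp,
        means=table.means,
        scales=table.scales,
    )


@dataclass
class ClassMap:
    """Categorical class-index raster plus its catalogue and provenance."""

    data: np.ndarray                    # int indices into catalogue, -1 nodata
    catalogue: ClassCatalogue
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    tag: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        vals = np.unique(self.data)
        bad = [int(v) for v in vals
               if v != NODATA_CLASS and not 0 <= v < len(self.catalogue)]
        if bad:
            raise ValueError(f"class indices outside the catalogue: {bad}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def class_name(self, index: int) -> str:
        return self.catalogue.classes[index]

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Class index at each world point (-1 outside or nodata)."""
        col = np.floor((np.asarray(x) - self.origin[0]) / self.pixel_size).astype(int)
        row = np.floor((self.origin[1] - np.asarray(y)) / self.pixel_size).astype(int)
        out = np.full(col.shape, NODATA_CLASS, dtype=int)
        ok = (row >= 0) & (row < self.shape[0]) & (col >= 0) & (col < self.shape[1])
        out[ok] = self.data[row[ok], col[ok]]
        return out


def predict_map(
    model: TrainedClassifier,
    features: FeatureStack,
    catalogue: ClassCatalogue | None = None,
) -> ClassMap:
    """Apply the forest to a feature stack, pixel-wise.

    Features are standardised with the parameters stored on the model;
    any pixel with a nodata feature becomes nodata (no imputation).
    """
    catalogue = catalogue if catalogue is not None else default_catalogue()
    missing = [n for n in model.feature_names if n not in features.names]
    if missing:
        raise ValueError(f"feature stack lacks model features: {missing}")
    mat = features.as_array(model.feature_names)
    if model.means is not None:
        mat = (mat - model.means) / model.scales
    valid = np.isfinite(mat).all(axis=1)
    out = np.full(mat.shape[0], NODATA_CLASS, dtype=np.int16)
    if valid.any():
        pred = model.model.predict(mat[valid])
        out[valid] = [catalogue.index(c) for c in pred]
    data = out.reshape(features.shape)
    return ClassMap(data, catalogue, features.pixel_size, features.origin,
                    tag=features.tag)


def majority_filter(class_map: ClassMap, window: int = 3) -> ClassMap:
    """Replace each pixel by the modal class of its window (single pass).

    Nodata neighbours are excluded from the vote; any tie for the modal
    class retains the centre pixel's class; nodata centres stay nodata.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    data = class_map.data
    n_classes = len(class_map.catalogue)
    counts = np.zeros((n_classes,) + data.shape, dtype=np.int32)
    kernel = np.ones((window, window), dtype=np.int32)
    for k in range(n_classes):
        counts[k] = ndimage.convolve((data == k).astype(np.int32), kernel,
                                     mode="constant", cval=0)
    max_count = counts.max(axis=0)
    winner = counts.argmax(axis=0)
    tie = (counts == max_count).sum(axis=0) > 1

    centre_ok = data != NODATA_CLASS
    out = np.where(tie, data, winner)
    out = np.where(centre_ok, out, NODATA_CLASS).astype(data.dtype)
    return ClassMap(out, class_map.catalogue, class_map.pixel_size,
                    class_map.origin, class_map.tag)


@dataclass
class ImportanceTable:
    """Overall and per-class feature importance scores."""

    overall: pd.Series                       # index: feature names
    per_class: pd.DataFrame                  # features x classes
    top5: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        out = self.per_class.copy()
        out.insert(0, "overall", self.overall)
        return out


def per_class_importance(model: TrainedClassifier, table: TrainingTable) -> ImportanceTable:
    """Per-class importance via the product rule.

    score(class c, feature f) = overall_importance(f) * |mean of the
    standardised feature f over the training pixels of class c|. The
    top-5 features per class are ranked by score.
    """
    if not table.standardized:
        raise ValueError("training table must be standardised")
    if list(table.feature_names) != list(model.feature_names):
        raise ValueError("table and model feature lists differ")
    overall = pd.Series(model.importances, index=model.feature_names, name="overall")

    classes = [c for c in model.classes]
    scores = {}
    for c in classes:
        rows = table.y == c
        if not rows.any():
            raise ValueError(f"class {c!r} absent from the training table")
        class_mean = np.abs(table.X[rows].mean(axis=0))
        scores[c] = overall.to_numpy() * class_mean
    per_class = pd.DataFrame(scores, index=model.feature_names)
    top5 = {
        c: per_class[c].sort_values(ascending=False).head(5).index.tolist()
        for c in classes
    }
    return ImportanceTable(overall, per_class, top5)
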