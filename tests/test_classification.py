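"""Random-forest training, raster prediction, majority filtering and
importance decomposition."""

import numpy as np
import pytest

from peatstack.catalogue import default_catalogue
from peatstack.classify import (ClassMap, NODATA_CLASS, majority_filter,
                                per_class_importance, predict_map, train_rf)
from peatstack.grids import FeatureStack
from peatstack.selection import TrainingTable, standardize

CAT = default_catalogue()


def _separable_table(n=60, seed=1):
    """Two classes with disjoint single-feature supports."""
    rng = np.random.default_rng(seed)
    X = np.concatenate([rng.uniform(0, 1, n // 2), rng.uniform(5, 6, n // 2)])
    y = np.array(["water"] * (n // 2) + ["rubber"] * (n // 2))
    return standardize(TrainingTable(X[:, None], y, ["f"]))


class TestTrainRF:
    def test_requires_standardised_table(self):
        t = TrainingTable(np.zeros((4, 1)), np.array(list("aabb")), ["f"])
        with pytest.raises(ValueError, match="standardised"):
            train_rf(t)

    def test_mtry_exceeding_features_rejected(self):
        with pytest.raises(ValueError, match="mtry"):
            train_rf(_separable_table(), mtry=5)

    def test_single_class_always_predicted(self):
        t = standardize(TrainingTable(np.random.default_rng(0).normal(size=(10, 2)),
                                      np.array(["water"] * 10), ["f0", "f1"]))
        model = train_rf(t, mtry=2, seed=1)
        assert set(model.model.predict(t.X)) == {"water"}

    def test_separable_classes_perfect_holdout(self):
        table = _separable_table(seed=1)
        model = train_rf(table, mtry=1, seed=1)
        rng = np.random.default_rng(99)
        X_new = np.concatenate([rng.uniform(0, 1, 20), rng.uniform(5, 6, 20)])
        X_new = (X_new[:, None] - table.means) / table.scales
        pred = model.model.predict(X_new)
        assert (pred == np.array(["water"] * 20 + ["rubber"] * 20)).all()

    def test_importances_sum_to_one(self):
        table = _separable_table()
        model = train_rf(table, mtry=1, seed=2)
        assert abs(model.importances.sum() - 1.0) < 1e-9
        assert (model.importances >= 0).all()

    def test_deterministic_under_seed(self):
        table = _separable_table()
        a = train_rf(table, mtry=1, seed=3)
        b = train_rf(table, mtry=1, seed=3)
        np.testing.assert_array_equal(a.importances, b.importances)


class TestPredictMap:
    def _model_and_stack(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 0.1, (30, 2)), rng.normal(4, 0.1, (30, 2))])
        y = np.array(["water"] * 30 + ["rubber"] * 30)
        table = standardize(TrainingTable(X, y, ["f0", "f1"]))
        model = train_rf(table, mtry=2, seed=5)
        stack = FeatureStack({"f0": np.full((5, 5), 4.0),
                              "f1": np.full((5, 5), 4.0)}, 20.0)
        return model, stack

    def test_uniform_features_uniform_map(self):
        model, stack = self._model_and_stack()
        cmap = predict_map(model, stack, CAT)
        assert (cmap.data == CAT.index("rubber")).all()

    def test_predictions_in_class_list(self, small_scene, composites):
        from peatstack.features import assemble_combination
        from peatstack.selection import extract_training_pixels
        optical, radar = composites
        feats = assemble_combination("S2", optical=optical)
        table = standardize(extract_training_pixels(feats, small_scene.reference))
        model = train_rf(table, seed=0)
        cmap = predict_map(model, feats, CAT)
        assert set(np.unique(cmap.data)) <= set(range(12)) | {NODATA_CLASS}

    def test_nodata_feature_gives_nodata_pixel(self):
        model, stack = self._model_and_stack()
        stack.features["f0"][2, 2] = np.nan
        cmap = predict_map(model, stack, CAT)
        assert cmap.data[2, 2] == NODATA_CLASS
        assert (cmap.data != NODATA_CLASS).sum() == 24

    def test_feature_mismatch_errors(self):
        model, _ = self._model_and_stack()
        with pytest.raises(ValueError, match="lacks"):
            predict_map(model, FeatureStack({"other": np.zeros((2, 2))}, 20.0), CAT)

    def test_training_pixels_high_self_accuracy(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(k * 4, 0.1, (20, 2)) for k in range(3)])
        y = np.array(["water"] * 20 + ["rubber"] * 20 + ["coconut"] * 20)
        table = standardize(TrainingTable(X, y, ["f0", "f1"]))
        model = train_rf(table, mtry=2, seed=8)
        assert (model.model.predict(table.X) == y).mean() >= 0.99


class TestMajorityFilter:
    def _map(self, data):
        return ClassMap(np.asarray(data, dtype=np.int16), CAT, 20.0)

    def test_uniform_map_unchanged(self):
        cmap = self._map(np.full((5, 5), 3))
        out = majority_filter(cmap)
        np.testing.assert_array_equal(out.data, cmap.data)

    def test_salt_pixel_removed(self):
        data = np.full((5, 5), 2)
        data[2, 2] = 7
        out = majority_filter(self._map(data))
        assert out.data[2, 2] == 2

    def test_perfect_tie_retains_centre(self):
        # centre class 5; neighbours 4x class 0 and 4x class 1
        data = np.array([[0, 0, 1],
                         [0, 5, 1],
                         [1, 0, 1]])
        out = majority_filter(self._map(data))
        assert out.data[1, 1] == 5

    def test_never_introduces_new_class(self, small_scene):
        truth = small_scene.truth
        cmap = ClassMap(truth.data, CAT, truth.pixel_size, truth.origin)
        out = majority_filter(cmap)
        assert set(np.unique(out.data)) <= set(np.unique(cmap.data))

    def test_idempotent_on_strict_majorities(self):
        data = np.zeros((6, 6), dtype=np.int16)
        data[:, 3:] = 4
        once = majority_filter(self._map(data))
        twice = majority_filter(once)
        np.testing.assert_array_equal(once.data, twice.data)

    def test_nodata_centre_stays_nodata(self):
        data = np.full((3, 3), 2)
        data[1, 1] = NODATA_CLASS
        out = majority_filter(self._map(data))
        assert out.data[1, 1] == NODATA_CLASS


class TestPerClassImportance:
    def _table_and_model(self, shift_elev_for="water", seed=7):
        rng = np.random.default_rng(seed)
        names = ["NDVI", "VV", "Elevation"]
        classes = ["water", "rubber", "coconut"]
        X_rows, y_rows = [], []
        for k, cls in enumerate(classes):
            block = rng.normal(size=(40, 3))
            block[:, 0] += k  # NDVI separates the classes
            if cls == shift_elev_for:
                block[:, 2] += 3.0
            X_rows.append(block)
            y_rows += [cls] * 40
        table = standardize(TrainingTable(np.vstack(X_rows), np.array(y_rows),
                                          names))
        return table, train_rf(table, mtry=2, seed=seed)

    def test_product_rule_single_feature(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(0, 0.1, 30), rng.normal(2, 0.1, 30)])
        table = standardize(TrainingTable(
            X[:, None], np.array(["water"] * 30 + ["rubber"] * 30), ["f"]))
        model = train_rf(table, mtry=1, seed=0)
        imp = per_class_importance(model, table)
        # single feature: overall importance 1, score = |class z-mean|
        want = abs(table.X[table.y == "water"].mean())
        np.testing.assert_allclose(imp.per_class.loc["f", "water"], want, atol=1e-9)

    def test_zero_class_mean_zero_score(self):
        table, model = self._table_and_model()
        # force one class mean to zero on one feature
        rows = table.y == "rubber"
        table.X[rows, 1] -= table.X[rows, 1].mean()
        imp = per_class_importance(model, table)
        assert imp.per_class.loc["VV", "rubber"] == pytest.approx(0.0, abs=1e-12)

    def test_elevation_shift_ranks_first(self):
        table, model = self._table_and_model(shift_elev_for="water")
        imp = per_class_importance(model, table)
        assert imp.top5["water"][0] == "Elevation"

    def test_invariant_to_other_class_relabelling(self):
        table, model = self._table_and_model()
        imp1 = per_class_importance(model, table)
        relabeled = TrainingTable(
            table.X, np.where(table.y == "coconut", "oil palm", table.y),
            list(table.feature_names), table.tag, table.means, table.scales,
            table.zero_variance, True)
        # per-class scores for untouched classes depend only on their rows
        imp2_scores = (model.importances
                       * np.abs(relabeled.X[relabeled.y == "water"].mean(axis=0)))
        np.testing.assert_allclose(imp1.per_class["water"].to_numpy(),
                                   imp2_scores, atol=1e-12)
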