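"""Vegetation indices, texture statistics, temporal amplitude, terrain
features and dataset-combination assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peatstack.features import (COMBINATIONS, GLCMSpec, OPTICAL_BANDS,
                                assemble_combination, glcm_features,
                                temporal_amplitude, terrain_features,
                                vegetation_indices, window_stddev)
from peatstack.grids import ImageTimeSeries, RasterGrid, SceneStack


def _optical(**values):
    bands = {name: np.full((2, 2), values.get(name, 0.2)) for name in OPTICAL_BANDS}
    return SceneStack(bands, 20.0)


class TestVegetationIndices:
    def test_ndvi_zero_when_nir_equals_red(self):
        vi = vegetation_indices(_optical(NIR=0.3, Red=0.3))
        np.testing.assert_allclose(vi.layer("NDVI"), 0.0)

    def test_s2rep_hand_value(self):
        vi = vegetation_indices(_optical(Red=0.1, RedEdge1=0.3, RedEdge2=0.5,
                                         RedEdge3=0.7))
        np.testing.assert_allclose(vi.layer("S2REP"), 722.5)

    def test_msavi2_zero_when_nir_equals_red(self):
        vi = vegetation_indices(_optical(NIR=0.5, Red=0.5))
        np.testing.assert_allclose(vi.layer("MSAVI2"), 0.0, atol=1e-12)

    def test_evi_hand_value(self):
        vi = vegetation_indices(_optical(NIR=0.4, Red=0.2, Blue=0.1))
        np.testing.assert_allclose(vi.layer("EVI"), 0.5 / 1.85, atol=1e-4)

    def test_zero_denominator_becomes_nodata(self):
        vi = vegetation_indices(_optical(NIR=0.0, Red=0.0))
        assert np.isnan(vi.layer("NDVI")).all()

    def test_missing_band_errors(self):
        bands = {n: np.zeros((2, 2)) for n in OPTICAL_BANDS if n != "SWIR2"}
        with pytest.raises(KeyError, match="SWIR2"):
            vegetation_indices(SceneStack(bands, 20.0))

    @given(st.integers(0, 10**6))
    @settings(max_examples=25, deadline=None)
    def test_normalised_differences_bounded(self, seed):
        rng = np.random.default_rng(seed)
        bands = {n: rng.uniform(0.01, 1.0, size=(4, 4)) for n in OPTICAL_BANDS}
        vi = vegetation_indices(SceneStack(bands, 20.0))
        for name in ("NDVI", "NDWI", "LSWI", "NBR", "NBR2", "GNDVI"):
            layer = vi.layer(name)
            assert np.nanmin(layer) >= -1.0 - 1e-12
            assert np.nanmax(layer) <= 1.0 + 1e-12


def window_sd_oracle(arr, window):
    r = window // 2
    padded = np.pad(arr, r, mode="reflect")
    out = np.empty_like(arr, dtype=float)
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            block = padded[i:i + window, j:j + window].ravel()
            block = block[~np.isnan(block)]
            out[i, j] = block.std() if len(block) else np.nan
    return out


class TestWindowStddev:
    def test_constant_raster_is_zero(self):
        assert window_stddev(np.full((7, 7), 3.0)).max() == 0.0

    def test_single_one_among_zeros(self):
        arr = np.zeros((9, 9))
        arr[4, 4] = 1.0
        out = window_stddev(arr, 5)
        want = np.sqrt(24.0 / 625.0)
        np.testing.assert_allclose(out[4, 4], want, atol=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        arr = rng.normal(size=(20, 20))
        arr[3, 4] = np.nan
        out = window_stddev(arr, 5)
        want = window_sd_oracle(arr, 5)
        np.testing.assert_allclose(out, want, atol=1e-12)

    def test_window_larger_than_raster_rejected(self):
        with pytest.raises(ValueError):
            window_stddev(np.zeros((3, 3)), 5)


def glcm_oracle(layer, spec):
    """Brute-force GLCM: build the normalised matrix per pixel and take
    the textbook statistics from it."""
    arr = np.asarray(layer, dtype=float)
    valid = np.isfinite(arr)
    lo, hi = arr[valid].min(), arr[valid].max()
    if hi == lo:
        q = np.zeros(arr.shape)
    else:
        q = np.clip(np.floor((arr - lo) / (hi - lo) * spec.levels), 0,
                    spec.levels - 1)
    q[~valid] = np.nan
    kr = spec.kernel // 2
    pad = kr + spec.distance
    qp = np.pad(q, pad, mode="reflect")

    out = {k: np.full(arr.shape, np.nan) for k in
           ("contrast", "correlation", "variance")}
    for r in range(arr.shape[0]):
        for c in range(arr.shape[1]):
            P = np.zeros((spec.levels, spec.levels))
            for ky in range(-kr, kr + 1):
                for kx in range(-kr, kr + 1):
                    y, x = pad + r + ky, pad + c + kx
                    a = qp[y, x]
                    for dy, dx in spec.offsets:
                        b = qp[y + dy, x + dx]
                        if np.isnan(a) or np.isnan(b):
                            continue
                        P[int(a), int(b)] += 1
                        P[int(b), int(a)] += 1
            total = P.sum()
            if total == 0:
                continue
            P /= total
            assert abs(P.sum() - 1.0) < 1e-12
            i, j = np.indices(P.shape)
            mu_i = (P * i).sum()
            mu_j = (P * j).sum()
            var_i = (P * (i - mu_i) ** 2).sum()
            var_j = (P * (j - mu_j) ** 2).sum()
            out["contrast"][r, c] = (P * (i - j) ** 2).sum()
            denom = np.sqrt(var_i * var_j)
            out["correlation"][r, c] = (
                (P * (i - mu_i) * (j - mu_j)).sum() / denom if denom > 0 else 0.0
            )
            out["variance"][r, c] = (P * (i - mu_i) ** 2).sum()
    return out


class TestGLCM:
    def test_matches_bruteforce_oracle(self, rng):
        arr = rng.normal(size=(20, 20))
        spec = GLCMSpec(levels=8, distance=4)
        got = glcm_features(arr, spec)
        want = glcm_oracle(arr, spec)
        for stat in ("contrast", "correlation", "variance"):
            np.testing.assert_allclose(got[stat], want[stat], atol=1e-12)

    def test_constant_layer_zero_contrast_and_variance(self):
        got = glcm_features(np.full((12, 12), 7.0), GLCMSpec(levels=4, distance=2))
        assert np.nanmax(got["contrast"]) == 0.0
        assert np.nanmax(got["variance"]) == 0.0

    def test_checkerboard_contrast(self):
        """At distance 1 the two axis directions always pair opposite
        levels (contrast 1) and the diagonals pair equal levels
        (contrast 0): the 4-direction mean is 0.5."""
        cb = (np.indices((14, 14)).sum(axis=0) % 2).astype(float)
        got = glcm_features(cb, GLCMSpec(levels=2, distance=1))
        np.testing.assert_allclose(got["contrast"][7, 7], 0.5)

    def test_correlation_bounded_variance_nonneg(self, rng):
        arr = rng.random((15, 15))
        got = glcm_features(arr, GLCMSpec(levels=6, distance=3))
        assert np.nanmin(got["variance"]) >= 0
        assert np.nanmin(got["contrast"]) >= 0
        assert np.nanmax(np.abs(got["correlation"])) <= 1 + 1e-9

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            GLCMSpec(levels=1)


class TestTemporalAmplitude:
    def _series(self, values):
        return ImageTimeSeries([
            SceneStack({"VV": np.full((2, 2), float(v))}, 10.0, timestamp=float(i))
            for i, v in enumerate(values)
        ])

    def test_constant_series_zero(self):
        amp = temporal_amplitude(self._series([4, 4, 4]), "VV")
        np.testing.assert_allclose(amp.data, 0.0)

    def test_eleven_point_series(self):
        amp = temporal_amplitude(self._series(range(11)), "VV")
        np.testing.assert_allclose(amp.data, 8.0)

    def test_two_point_closed_form(self):
        amp = temporal_amplitude(self._series([2.0, 7.0]), "VV")
        np.testing.assert_allclose(amp.data, 0.8 * 5.0)

    def test_matches_percentile_oracle(self, rng):
        data = rng.normal(size=(9, 6, 6))
        series = ImageTimeSeries([
            SceneStack({"VV": data[t]}, 10.0, timestamp=float(t)) for t in range(9)
        ])
        amp = temporal_amplitude(series, "VV")
        want = np.percentile(data, 90, axis=0) - np.percentile(data, 10, axis=0)
        np.testing.assert_allclose(amp.data, want, atol=1e-12)
        assert (amp.data >= 0).all()

    def test_unknown_band_errors(self):
        with pytest.raises(KeyError, match="VH"):
            temporal_amplitude(self._series([1, 2]), "VH")


class TestTerrain:
    def test_flat_dem(self):
        tf = terrain_features(RasterGrid(np.full((6, 6), 12.0), 30.0))
        assert tf.layer("Slope").max() == 0.0
        assert np.isnan(tf.layer("Aspect")).all()
        np.testing.assert_array_equal(tf.layer("Elevation"), 12.0)

    def test_unit_plane_slope_45_degrees(self):
        x = np.tile(np.arange(8, dtype=float), (8, 1))  # 1 m rise per 1 m east
        tf = terrain_features(RasterGrid(x, 1.0))
        np.testing.assert_allclose(tf.layer("Slope")[2:-2, 2:-2], 45.0)

    def test_east_rising_plane_faces_west(self):
        x = np.tile(np.arange(8, dtype=float), (8, 1))
        tf = terrain_features(RasterGrid(x, 1.0))
        np.testing.assert_allclose(tf.layer("Aspect")[2:-2, 2:-2], 270.0)


class TestAssembleCombination:
    def test_feature_lists_match_catalogued_combinations(
            self, small_scene, composites):
        optical, radar = composites
        expected_counts = {"S2": 10, "S2+": 21, "S1": 2, "S1+": 12,
                           "S2+S1+": 33, "S2+S1+DEM": 36}
        for tag, count in expected_counts.items():
            stack = assemble_combination(
                tag, optical=optical, radar=radar,
                radar_series=small_scene.radar_series, dem=small_scene.dem)
            assert stack.names == COMBINATIONS[tag]
            assert len(stack) == count
            assert stack.tag == tag

    def test_s1_is_exactly_the_two_polarisations(self, composites):
        _, radar = composites
        stack = assemble_combination("S1", radar=radar)
        assert stack.names == ("VH", "VV")

    def test_missing_input_errors(self, composites):
        optical, _ = composites
        with pytest.raises(ValueError, match="radar"):
            assemble_combination("S1+", optical=optical)

    def test_unknown_tag_rejected(self):
        with pytest.raises(ValueError):
            assemble_combination("S3")
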