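"""Vegetation indices, GLCM texture (vs a brute-force oracle), assembly."""

import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon, box

from tealai.features import (DIRECTION_OFFSETS, FEATURE_COLUMNS,
                             TEXTURE_METRICS, VI_NAMES, CanopySample,
                             FeatureTable, assemble_features,
                             canopy_mean_reflectance, canopy_texture,
                             glcm_texture, normalize_features, quantize,
                             stack_texture, vegetation_indices)
from tealai.raster import BAND_NAMES, Georeference, ReflectanceStack

from conftest import uniform_stack


class TestVegetationIndices:
    BASE = {"Blue": 0.06373, "Green": 0.10965, "Red": 0.05311,
            "RedEdge": 0.20555, "NIR": 0.25790}

    def test_ndvi_at_reference_band_means(self):
        vis = vegetation_indices(self.BASE)
        assert vis["NDVI"] == pytest.approx(0.6585, abs=1e-4)

    def test_all_sixteen_present_and_finite(self):
        vis = vegetation_indices(self.BASE)
        assert set(vis) == set(VI_NAMES)
        assert all(np.isfinite(v) for v in vis.values())

    def test_nir_equals_red_reductions(self):
        means = dict(self.BASE, NIR=0.1, Red=0.1)
        vis = vegetation_indices(means)
        assert vis["NDVI"] == 0.0 and vis["DVI"] == 0.0 and vis["SR"] == 1.0

    def test_simple_ratio_and_difference(self):
        vis = vegetation_indices(dict(self.BASE, NIR=0.2, Red=0.1))
        assert vis["SR"] == pytest.approx(2.0)
        assert vis["DVI"] == pytest.approx(0.1)

    def test_stated_constants(self):
        """SAVI (L=0.5), EVI (g=2.5, C1=6, C2=7.5, L=1), OSAVI (0.16)."""
        b, g, r, re, nir = (self.BASE[k] for k in BAND_NAMES)
        vis = vegetation_indices(self.BASE)
        assert vis["SAVI"] == pytest.approx(1.5 * (nir - r) / (nir + r + 0.5))
        assert vis["EVI"] == pytest.approx(
            2.5 * (nir - r) / (nir + 6 * r - 7.5 * b + 1))
        assert vis["OSAVI"] == pytest.approx((nir - r) / (nir + r + 0.16))

    def test_zero_denominator_flagged_nan(self):
        means = dict(self.BASE, Green=0.1, Red=0.1, Blue=0.2)  # G+R-B = 0
        assert math.isnan(vegetation_indices(means)["VARI"])

    def test_normalized_difference_indices_bounded(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            means = {k: float(v) for k, v in
                     zip(BAND_NAMES, rng.uniform(0.01, 0.9, 5))}
            vis = vegetation_indices(means)
            for name in ("NDVI", "GNDVI", "NDRE"):
                assert -1.0 <= vis[name] <= 1.0


def oracle_window_metrics(q, center, offset, levels):
    """Exhaustive pair-enumeration GLCM for one 3x3 window, one direction.

    Independent of the production code: explicitly builds the symmetric
    normalized co-occurrence dictionary from every in-window pixel pair,
    then evaluates the Haralick formulas over its cells.
    """
    r0, c0 = center
    dr, dc = offset
    rows, cols = q.shape
    counts = {}
    for a in (-1, 0, 1):
        for b in (-1, 0, 1):
            r1, c1 = r0 + a, c0 + b
            r2, c2 = r1 + dr, c1 + dc
            if not (abs(a + dr) <= 1 and abs(b + dc) <= 1):
                continue  # partner leaves the window
            if not (0 <= r1 < rows and 0 <= c1 < cols
                    and 0 <= r2 < rows and 0 <= c2 < cols):
                continue  # window truncated at the raster edge
            i, j = q[r1, c1], q[r2, c2]
            if i < 0 or j < 0:
                continue
            counts[(i, j)] = counts.get((i, j), 0) + 1
            counts[(j, i)] = counts.get((j, i), 0) + 1
    total = sum(counts.values())
    if total < 4:  # fewer than 2 valid pairs
        return None
    p = {k: v / total for k, v in counts.items()}
    mean = sum(i * w for (i, _), w in p.items())
    var = sum((i - mean) ** 2 * w for (i, _), w in p.items())
    out = {
        "Mean": mean,
        "Variance": var,
        "Homogeneity": sum(w / (1 + (i - j) ** 2) for (i, j), w in p.items()),
        "Contrast": sum(w * (i - j) ** 2 for (i, j), w in p.items()),
        "Dissimilarity": sum(w * abs(i - j) for (i, j), w in p.items()),
        "Entropy": -sum(w * math.log(w) for w in p.values()),
        "SecondMoment": sum(w * w for w in p.values()),
        "Correlation": (sum((i - mean) * (j - mean) * w
                            for (i, j), w in p.items()) / var
                        if var > 0 else 0.0),
    }
    return out


class TestGLCM:
    def test_constant_window_metrics(self):
        band = np.zeros((5, 5))
        band[0, 0] = 1.0  # give the band dynamic range; far corner only
        metrics = glcm_texture(band)
        # Center pixel's windows are all-constant at level 0.
        assert metrics["Contrast"][2, 2] == 0.0
        assert metrics["Dissimilarity"][2, 2] == 0.0
        assert metrics["Homogeneity"][2, 2] == 1.0
        assert metrics["SecondMoment"][2, 2] == 1.0
        assert metrics["Entropy"][2, 2] == 0.0
        assert metrics["Correlation"][2, 2] == 0.0  # zero-variance convention

    def test_checkerboard_horizontal_direction(self):
        """Two-level checkerboard, 0-degree offset: every horizontal pair is
        (0,1) or (1,0); oracle counts confirm each metric."""
        board = np.indices((6, 6)).sum(axis=0) % 2
        q = quantize(board.astype(float), levels=64)
        center = (3, 3)
        oracle = oracle_window_metrics(q, center, DIRECTION_OFFSETS[0], 64)
        lv = 63  # two quantized levels: 0 and 63
        assert oracle["Contrast"] == pytest.approx(lv ** 2)
        assert oracle["Dissimilarity"] == pytest.approx(lv)
        assert oracle["Correlation"] == pytest.approx(-1.0)
        assert oracle["SecondMoment"] == pytest.approx(0.5)
        assert oracle["Entropy"] == pytest.approx(math.log(2))

    def test_oracle_equivalence_on_seeded_image(self):
        """All 8 metrics x 4 directions match exhaustive pair enumeration on
        every window of a seeded 16x16 image."""
        rng = np.random.default_rng(16)
        band = rng.uniform(0.02, 0.4, (16, 16))
        band[3, 4] = np.nan  # exercise invalid-pixel handling
        q = quantize(band, 64)
        from tealai.features import _direction_metrics
        for d, offset in DIRECTION_OFFSETS.items():
            got = _direction_metrics(q, offset, 64)
            for r in range(16):
                for c in range(16):
                    exp = oracle_window_metrics(q, (r, c), offset, 64)
                    for metric in TEXTURE_METRICS:
                        if exp is None:
                            assert np.isnan(got[metric][r, c]), (d, r, c, metric)
                        else:
                            assert got[metric][r, c] == pytest.approx(
                                exp[metric], abs=1e-10), (d, r, c, metric)

    def test_direction_average_invariant_to_ordering(self):
        rng = np.random.default_rng(4)
        band = rng.uniform(0, 1, (10, 10))
        a = glcm_texture(band, directions=(0, 45, 90, 135))
        b = glcm_texture(band, directions=(135, 90, 0, 45))
        for metric in TEXTURE_METRICS:
            assert np.allclose(a[metric], b[metric], equal_nan=True)

    def test_constant_band_raises(self):
        with pytest.raises(ValueError, match="dynamic range"):
            glcm_texture(np.full((8, 8), 0.3))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            glcm_texture(np.random.default_rng(0).uniform(0, 1, (8, 8)),
                         window=4)


class TestCanopyAggregation:
    def georef(self, n=20):
        return Georeference(0.0, float(n), 1.0)

    def test_uniform_stack_mean(self):
        stack = uniform_stack((20, 20), dict.fromkeys(BAND_NAMES, 0.2),
                              self.georef())
        s = CanopySample("a", Point(10.0, 10.0))
        means = canopy_mean_reflectance(stack, s, point_buffer=2.0)
        assert all(v == pytest.approx(0.2) for v in means.values())

    def test_two_pixel_polygon_mean(self):
        stack = uniform_stack((20, 20), georef=self.georef())
        stack.bands[:, 5, 5] = 0.1
        stack.bands[:, 5, 6] = 0.3
        poly = box(5.0, 14.0, 7.0, 15.0)  # covers exactly pixels (5,5),(5,6)
        means = canopy_mean_reflectance(stack, CanopySample("a", poly))
        assert means["Blue"] == pytest.approx(0.2)

    def test_polygon_outside_raster_raises(self):
        stack = uniform_stack((20, 20), georef=self.georef())
        with pytest.raises(ValueError, match="no valid pixels"):
            canopy_mean_reflectance(stack, CanopySample("a", Point(-50.0, -50.0)))

    def test_masked_texture_pixels_excluded(self):
        grid = np.full((20, 20), 0.4)
        grid[5, 5] = np.nan
        grid[5, 6] = 0.6
        texture = {"Blue": {"Mean": grid}}
        poly = box(5.0, 14.0, 7.0, 15.0)
        vals = canopy_texture(texture, CanopySample("a", poly), self.georef(),
                              (20, 20))
        assert vals["Mean_Blue"] == pytest.approx(0.6)


@pytest.fixture(scope="module")
def small_scene():
    rng = np.random.default_rng(12)
    georef = Georeference(0.0, 24.0, 1.0)
    bands = np.stack([
        np.clip(rng.normal(level, 0.02, (24, 24)), 0.01, 1)
        for level in (0.06, 0.11, 0.05, 0.2, 0.26)])
    stack = ReflectanceStack(bands, BAND_NAMES,
                             np.ones((24, 24), bool), georef)
    samples = [CanopySample(f"s{i}", Point(5.0 + 6 * i, 12.0), float(1 + i))
               for i in range(3)]
    return stack, samples


class TestAssembleNormalize:
    def test_table_has_61_features(self, small_scene):
        stack, samples = small_scene
        table = assemble_features(samples, stack, point_buffer=2.0)
        assert list(table.features.columns) == list(FEATURE_COLUMNS)
        assert len(FEATURE_COLUMNS) == 5 + 16 + 40 == 61
        assert len(table.data) == 3
        assert table.data["reference_lai"].tolist() == [1.0, 2.0, 3.0]

    def test_duplicate_sample_id_raises(self, small_scene):
        stack, samples = small_scene
        dupes = samples + [CanopySample("s0", Point(12.0, 18.0))]
        with pytest.raises(ValueError, match="duplicated"):
            assemble_features(dupes, stack)

    def test_table_rejects_wrong_columns(self):
        with pytest.raises(ValueError, match="missing columns"):
            FeatureTable(pd.DataFrame({"NDVI": [0.5]}))

    def test_normalization_endpoints(self):
        base = {c: [float(i) for i in (0, 5, 10)] for c in FEATURE_COLUMNS}
        base["reference_lai"] = [1.0, 2.0, 3.0]
        table = FeatureTable(pd.DataFrame(base, index=["a", "b", "c"]))
        norm = normalize_features(table)
        assert norm.data.loc["a", "NDVI"] == -1.0
        assert norm.data.loc["b", "NDVI"] == 0.0
        assert norm.data.loc["c", "NDVI"] == 1.0
        assert norm.norm_record["NDVI"] == (0.0, 10.0)

    def test_normalization_idempotent_with_matching_record(self):
        base = {c: [-1.0, 0.0, 1.0] for c in FEATURE_COLUMNS}
        base["reference_lai"] = [1.0, 2.0, 3.0]
        table = FeatureTable(pd.DataFrame(base, index=["a", "b", "c"]))
        norm = normalize_features(table)
        assert np.allclose(norm.features.to_numpy(), table.features.to_numpy())

    def test_held_out_rows_not_clipped(self):
        base = {c: [0.0, 5.0, 20.0] for c in FEATURE_COLUMNS}
        base["reference_lai"] = [1.0, 2.0, 3.0]
        table = FeatureTable(pd.DataFrame(base, index=["a", "b", "c"]))
        norm = normalize_features(table, fit_rows=["a", "b"])
        assert norm.data.loc["c", "NDVI"] == pytest.approx(7.0)  # > 1, unclipped

    def test_constant_feature_raises(self):
        base = {c: [1.0, 1.0] for c in FEATURE_COLUMNS}
        base["reference_lai"] = [1.0, 2.0]
        table = FeatureTable(pd.DataFrame(base, index=["a", "b"]))
        with pytest.raises(ValueError, match="constant"):
            normalize_features(table)
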