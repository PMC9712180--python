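"""Feature registry structure, histogram statistics, and texture feature values."""

import numpy as np
import pytest
from scipy import stats

from conftest import droi
from xlung import features, texture
from xlung.prep import RoiMask, Volume


class TestRegistry:
    def test_counts_per_family(self):
        counts = {}
        for d in features.REGISTRY:
            counts[d.family] = counts.get(d.family, 0) + 1
        assert counts == {
            "HIST": 17, "GLCM_avg": 26, "GLCM_merged": 26,
            "GLRLM_avg": 16, "GLRLM_merged": 16,
            "GLSZM": 16, "GLDZM": 16, "NGLDM": 16, "NGTDM": 5,
        }
        assert sum(counts.values()) == 154

    def test_figure_anchor_vcodes(self):
        assert features.NAME_OF["V1"] == "mean"
        assert features.NAME_OF["V2"] == "standard_deviation"
        assert features.NAME_OF["V4"] == "skewness"
        assert features.NAME_OF["V5"] == "kurtosis"
        assert features.NAME_OF["V16"] == "root_mean_square"
        assert (features.FAMILY_OF["V108"], features.NAME_OF["V108"]) == (
            "GLSZM", "gray_level_non_uniformity_normalized")
        assert (features.FAMILY_OF["V141"], features.NAME_OF["V141"]) == (
            "NGLDM", "dependence_count_non_uniformity")


def _vol_mask(values):
    arr = np.asarray(values, dtype=float).reshape(1, 1, -1)
    return Volume(arr, (1, 1, 1)), RoiMask(np.ones_like(arr, dtype=bool), (1, 1, 1))


class TestHistogram:
    def test_constant_roi(self):
        h = features.histogram_features(*_vol_mask([-444.0] * 5))
        assert h["mean"] == -444.0
        assert h["standard_deviation"] == 0.0
        assert h["root_mean_square"] == 444.0

    def test_three_point_example(self):
        h = features.histogram_features(*_vol_mask([-1000.0, -500.0, 0.0]))
        assert h["mean"] == -500.0
        assert h["standard_deviation"] == pytest.approx(500.0)  # sample, ddof=1

    def test_symmetric_values_zero_skew(self):
        h = features.histogram_features(*_vol_mask([-4, -2, 0, 2, 4]))
        assert h["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_against_scipy_on_random_values(self):
        rng = np.random.default_rng(9)
        x = rng.gamma(2.0, 80.0, size=400) - 900.0
        h = features.histogram_features(*_vol_mask(x))
        assert h["skewness"] == pytest.approx(stats.skew(x))
        assert h["kurtosis"] == pytest.approx(stats.kurtosis(x, fisher=False))
        assert h["median"] == pytest.approx(np.median(x))
        assert h["energy"] == pytest.approx(np.sum(x**2))
        assert h["interquartile_range"] == pytest.approx(
            np.percentile(x, 75) - np.percentile(x, 25))

    def test_kurtosis_is_non_excess(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=20000)
        h = features.histogram_features(*_vol_mask(x))
        assert h["kurtosis"] == pytest.approx(3.0, abs=0.15)


class TestTextureFeatures:
    def test_constant_roi_glcm_limits(self):
        roi = droi(np.ones((3, 3, 3), dtype=int))
        f = features.glcm_features(texture.build_glcm(roi).merged())
        assert f["joint_entropy"] == 0.0
        assert f["joint_maximum"] == 1.0
        assert f["angular_second_moment"] == 1.0

    def test_stripe_glcm_contrast(self):
        # normalized stripe matrix: p(1,2) = p(2,1) = 0.5 -> contrast = 1
        roi = droi([1, 2, 1, 2])
        m = texture.build_glcm(roi).directional[(0, 0, 1)]
        f = features.glcm_features(m)
        assert f["contrast"] == pytest.approx(1.0)
        assert f["dissimilarity"] == pytest.approx(1.0)
        assert f["joint_entropy"] == pytest.approx(1.0)  # two equal cells, log2

    def test_constant_roi_glszm_non_uniformity_normalized_is_one(self):
        roi = droi(np.full((3, 3, 3), 5, dtype=int), n_bins=24)
        szm = texture.build_glszm(roi)
        f = features._szm_style(szm.matrix, szm.n_voxels, "GLSZM")
        assert f["gray_level_non_uniformity_normalized"] == 1.0
        assert f["zone_size_entropy"] == 0.0

    def test_degenerate_single_level_never_nan(self):
        roi = droi(np.full((3, 3, 3), 1, dtype=int))
        vals = features.texture_features(texture.build_all(roi))
        assert all(np.isfinite(v) for v in vals.values())

    def test_glrlm_conservation_identity_in_features(self):
        # run percentage of a constant 1x1x4 line: 1 run of 4 voxels -> 0.25
        roi = droi([3, 3, 3, 3])
        glrlm = texture.build_glrlm(roi)
        f = features._szm_style(glrlm.directional[(0, 0, 1)], glrlm.n_voxels, "GLRLM")
        assert f["run_percentage"] == pytest.approx(0.25)


def _extract(volume, mask, **kw):
    return features.extract_features(volume, mask, target_mm=1.0, **kw)


class TestExtraction:
    def test_full_vector_on_phantom(self, small_volume):
        vol, mask = small_volume
        out = _extract(vol, mask)
        assert list(out.keys()) == features.FEATURE_IDS
        assert all(np.isfinite(v) for v in out.values())

    def test_deterministic(self, small_volume):
        vol, mask = small_volume
        a = _extract(vol, mask)
        b = _extract(vol, mask)
        assert a == b

    def test_rotation_invariance_of_merged_and_direction_free(self):
        rng = np.random.default_rng(21)
        data = rng.uniform(-900, 100, size=(10, 10, 10))
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[2:8, 2:8, 2:8] = True
        v = Volume(data, (1, 1, 1))
        m = RoiMask(mask, (1, 1, 1))
        vr = Volume(np.rot90(data, axes=(0, 1)).copy(), (1, 1, 1))
        mr = RoiMask(np.rot90(mask, axes=(0, 1)).copy(), (1, 1, 1))
        a = _extract(v, m)
        b = _extract(vr, mr)
        invariant_families = {"HIST", "GLCM_merged", "GLRLM_merged",
                              "GLSZM", "GLDZM", "NGLDM", "NGTDM"}
        for d in features.REGISTRY:
            if d.family in invariant_families:
                assert a[d.feature_id] == pytest.approx(
                    b[d.feature_id], rel=1e-9
                ), f"{d.feature_id} {d.family} {d.name}"

    def test_extract_all_columns_and_abort_contract(self, small_volume):
        from xlung.pipeline import ExtractionConfig

        vol, mask = small_volume
        cfg = ExtractionConfig(target_spacing_mm={"microct": 1.0})
        cohort = [dict(subject_id="s1", domain="microct", label="control",
                       observer=1, repeat=1, volume=vol, mask=mask)]
        table = features.extract_all(cohort, cfg)
        assert len(features.feature_columns(table)) == 154

        bad_mask = RoiMask(np.ones((5, 5, 5), dtype=bool), (1, 1, 1))
        cohort_bad = [dict(subject_id="broken", domain="microct", label="control",
                           observer=1, repeat=1, volume=vol, mask=bad_mask)]
        with pytest.raises(RuntimeError, match="broken"):
            features.extract_all(cohort_bad, cfg)
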