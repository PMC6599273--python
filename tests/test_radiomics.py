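"""Feature-extractor tests: catalogue contract, per-family oracles, and the
invariance properties (determinism, intensity shift, rotation, mask
restriction)."""

import numpy as np
import pytest

from mwradiomics.radiomics import (CATALOGUE, RadiomicsExtractor, extract_all,
                                   laws_features, wavelet_features)
from mwradiomics.radiomics.catalogue import build_catalogue
from mwradiomics.radiomics.firstorder import discretize, stat_features
from mwradiomics.radiomics.texture import (DIRECTIONS_13, glcm_matrix,
                                           run_length_matrix)
from mwradiomics.radiomics.wavelet import wavelet_subbands


class TestCatalogue:
    def test_contract_and_anchors(self):
        cat = build_catalogue()
        assert len(cat) == 364
        assert cat.family_counts() == {"ibsi": 209, "laws": 125, "wavelet": 30}
        assert cat["F8"].name == "stat_p10"
        assert cat["F19"].name == "stat_rms"
        assert cat["F44"].name == "ivh_vol_frac_90"
        assert cat["F87"].name == "morph_wcom_z"
        assert cat["F296"].name.startswith("wav_L2_")
        assert cat["F311"].name == "meta_voxel_dim_x"

    def test_order_stable(self):
        assert build_catalogue().names == CATALOGUE.names


@pytest.fixture()
def fixture_values():
    """100 fixed HU values spanning -600..60 (deterministic fixture)."""
    rng = np.random.default_rng(123)
    return rng.uniform(-600.0, 60.0, 100)


class TestFirstOrderOracles:
    def test_p10_matches_sorting_oracle(self, fixture_values):
        feats = stat_features(fixture_values)
        # independent oracle: sort + linear interpolation at rank 0.1*(n-1)
        x = np.sort(fixture_values)
        pos = 0.10 * (len(x) - 1)
        lo = int(np.floor(pos))
        oracle = x[lo] + (pos - lo) * (x[lo + 1] - x[lo])
        assert feats["stat_p10"] == pytest.approx(oracle, rel=1e-12)

    def test_rms_matches_bruteforce(self, fixture_values):
        feats = stat_features(fixture_values)
        oracle = np.sqrt(sum(v * v for v in fixture_values) / len(fixture_values))
        assert feats["stat_rms"] == pytest.approx(oracle, rel=1e-12)

    def test_voxel_dimension_features_are_metadata(self, sphere_mask):
        vol = np.full(sphere_mask.shape, 30.0)
        fv = extract_all(vol, sphere_mask, spacing=(2.5, 0.7, 0.7))
        assert fv.values["F311"] == 0.7   # voxel dim x
        assert fv.values["F313"] == 2.5   # voxel dim z
        assert fv.values["F314"] == pytest.approx(2.5 * 0.7 * 0.7)


class TestUniformAndSphere:
    def test_uniform_cube_degenerate_features(self):
        vol = np.full((12, 12, 12), 25.0)
        mask = np.zeros_like(vol, bool)
        mask[2:10, 2:10, 2:10] = True
        fv = extract_all(vol, mask, spacing=(1, 1, 1))
        assert fv.values["F2"] == 0.0  # intensity variance
        laws = laws_features(vol, mask)
        zero_sum = {k: v for k, v in laws.items() if k != "laws_L5L5L5"}
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in zero_sum.values())
        # L5 sums to 16, so the pure-level filter scales the constant by 16^3
        assert laws["laws_L5L5L5"] == pytest.approx(25.0 * 16 ** 3)

    def test_sphere_sphericity_near_one(self, sphere_mask):
        vol = np.full(sphere_mask.shape, 40.0)
        fv = extract_all(vol, sphere_mask, spacing=(1, 1, 1))
        assert fv.values[CATALOGUE["morph_sphericity"].code] == pytest.approx(
            1.0, abs=0.05)


class TestLaws:
    def test_offset_leaves_zero_sum_kernels_unchanged(self, part_solid_volume,
                                                      sphere_mask):
        a = laws_features(part_solid_volume, sphere_mask)
        b = laws_features(part_solid_volume + 100.0, sphere_mask)
        for k in a:
            if k == "laws_L5L5L5":
                continue
            assert a[k] == pytest.approx(b[k], rel=1e-9, abs=1e-9)

    def test_matches_direct_convolution_oracle(self):
        """E5 along x on a small grid equals a brute-force triple loop."""
        rng = np.random.default_rng(5)
        vol = rng.normal(0, 50, (7, 7, 7))
        mask = np.zeros((7, 7, 7), bool)
        mask[1:6, 1:6, 1:6] = True
        feats = laws_features(vol, mask)
        L5 = np.array([1, 4, 6, 4, 1.0])
        E5 = np.array([-1, -2, 0, 2, 1.0])

        def reflect(i, n):
            if i < 0:
                return -i - 1
            if i >= n:
                return 2 * n - i - 1
            return i

        def conv_at(z, y, x):
            acc = 0.0
            for a in range(-2, 3):
                for b in range(-2, 3):
                    for c in range(-2, 3):
                        acc += (L5[a + 2] * L5[b + 2] * E5[c + 2] *
                                vol[reflect(z + a, 7), reflect(y + b, 7),
                                    reflect(x + c, 7)])
            return acc

        oracle = np.mean([abs(conv_at(*idx)) for idx in np.argwhere(mask)])
        assert feats["laws_L5L5E5"] == pytest.approx(oracle, rel=1e-9)

    def test_sinusoid_responds_in_matched_orientation(self):
        # an x-axis sinusoid excites E5/S5 along x far more than along z
        z, y, x = np.mgrid[0:16, 0:16, 0:16]
        vol = 100.0 * np.sin(x * np.pi / 2)
        mask = np.ones_like(vol, bool)
        feats = laws_features(vol, mask)
        assert feats["laws_L5L5S5"] > 10 * feats["laws_S5L5L5"]

    def test_small_bbox_gives_missing(self):
        vol = np.zeros((10, 10, 10))
        mask = np.zeros_like(vol, bool)
        mask[4:6, 4:6, 4:6] = True  # bbox 2 voxels/axis < 5
        assert all(np.isnan(v) for v in laws_features(vol, mask).values())


class TestGLCM:
    def test_checkerboard_matches_pair_counting_oracle(self):
        # 2-level 3D checkerboard: all distance-1 axis-neighbour pairs differ
        z, y, x = np.mgrid[0:6, 0:6, 0:6]
        labels = ((z + y + x) % 2 + 1).astype(np.int64)
        for d in [(0, 0, 1), (1, 0, 0), (1, 1, 1)]:
            m = glcm_matrix(labels, 2, d)
            # brute-force pair counting
            oracle = np.zeros((2, 2))
            for idx in np.ndindex(labels.shape):
                j = tuple(i + o for i, o in zip(idx, d))
                if all(0 <= c < s for c, s in zip(j, labels.shape)):
                    oracle[labels[idx] - 1, labels[j] - 1] += 1
            oracle = oracle + oracle.T
            assert np.array_equal(m, oracle)

    def test_run_length_matrix_matches_line_oracle(self):
        rng = np.random.default_rng(8)
        labels = rng.integers(0, 4, (5, 5, 5)).astype(np.int64)
        # axis-aligned direction: brute-force line scan along x
        m = run_length_matrix(labels, 3, (0, 0, 1))
        oracle = np.zeros((3, 5))
        for z in range(5):
            for y in range(5):
                run_level, run_len = 0, 0
                for x in range(5):
                    lev = labels[z, y, x]
                    if lev == run_level:
                        run_len += 1
                    else:
                        if run_level > 0:
                            oracle[run_level - 1, run_len - 1] += 1
                        run_level, run_len = lev, 1
                if run_level > 0:
                    oracle[run_level - 1, run_len - 1] += 1
        assert np.array_equal(m[:, :5], oracle)

    def test_run_length_diagonal_direction(self):
        labels = np.ones((4, 4, 4), dtype=np.int64)
        m = run_length_matrix(labels, 1, (1, 1, 1))
        # main space diagonal has runs of length 4, 3, 3, ... over the cube
        total_voxels = (m[0] * np.arange(1, m.shape[1] + 1)).sum()
        assert total_voxels == 64
        assert m[0, 3] >= 1  # at least one full-length diagonal run


class TestWavelet:
    def test_constant_volume_zero_detail_energy(self):
        vol = np.full((12, 12, 12), 7.0)
        mask = np.ones_like(vol, bool)
        feats = wavelet_features(vol, mask)
        for k, v in feats.items():
            if "_aaa_" not in k and k.endswith("energy"):
                assert v == pytest.approx(0.0, abs=1e-12)

    def test_parseval_energy_conservation(self):
        rng = np.random.default_rng(17)
        vol = rng.normal(0, 1, (8, 8, 8))
        bands = wavelet_subbands(vol)
        total = sum(float((b ** 2).sum()) for b in bands.values())
        assert total == pytest.approx(float((vol ** 2).sum()), rel=1e-6)

    def test_white_noise_positive_energy_everywhere(self):
        rng = np.random.default_rng(19)
        vol = rng.normal(0, 30, (16, 16, 16))
        mask = np.ones_like(vol, bool)
        feats = wavelet_features(vol, mask)
        assert all(v > 0 for k, v in feats.items() if k.endswith("energy"))

    def test_small_bbox_gives_missing(self):
        vol = np.zeros((12, 12, 12))
        mask = np.zeros_like(vol, bool)
        mask[3:8, 3:8, 3:8] = True  # bbox 5 < 8
        assert all(np.isnan(v) for v in wavelet_features(vol, mask).values())


class TestExtractorProperties:
    def test_determinism(self, part_solid_volume, sphere_mask):
        ex = RadiomicsExtractor()
        a = ex.extract(part_solid_volume, sphere_mask, (1, 1, 1))
        b = ex.extract(part_solid_volume, sphere_mask, (1, 1, 1))
        assert a.values.equals(b.values)

    def test_intensity_shift_behaviour(self, part_solid_volume, sphere_mask):
        ex = RadiomicsExtractor()
        a = ex.extract(part_solid_volume, sphere_mask, (1, 1, 1)).values
        b = ex.extract(part_solid_volume + 50.0, sphere_mask, (1, 1, 1)).values
        # mean and percentiles shift by the offset
        for code in ("F1", "F5", "F8"):
            assert b[code] == pytest.approx(a[code] + 50.0, rel=1e-9)
        # variance-type features are invariant
        for name in ("stat_variance", "stat_iqr", "stat_sd"):
            code = CATALOGUE[name].code
            assert b[code] == pytest.approx(a[code], rel=1e-9)
        # geometric morphology is invariant
        for name in ("morph_volume_mm3", "morph_sphericity", "morph_extent",
                     "morph_major_axis"):
            code = CATALOGUE[name].code
            assert b[code] == pytest.approx(a[code], rel=1e-9)

    def test_rotation_invariance_direction_averaged(self):
        rng = np.random.default_rng(23)
        vol = rng.normal(-400, 120, (20, 20, 20))
        mask = np.zeros((20, 20, 20), bool)
        mask[4:16, 5:15, 3:17] = True
        ex = RadiomicsExtractor()
        a = ex.extract(vol, mask, (1, 1, 1)).values
        b = ex.extract(np.rot90(vol, axes=(1, 2)).copy(),
                       np.rot90(mask, axes=(1, 2)).copy(), (1, 1, 1)).values
        averaged = [d.code for d in CATALOGUE
                    if d.name.startswith(("glcm_d1", "glcm_d2", "glrlm_",
                                          "ngtdm_", "gldm_"))]
        for code in averaged:
            assert b[code] == pytest.approx(a[code], rel=1e-9, abs=1e-9), code

    def test_mask_restriction(self, part_solid_volume, sphere_mask):
        ex = RadiomicsExtractor()
        a = ex.extract(part_solid_volume, sphere_mask, (1, 1, 1)).values
        tampered = part_solid_volume.copy()
        tampered[0:2, 0:2, 0:2] = 500.0  # far outside mask + kernel support
        b = ex.extract(tampered, sphere_mask, (1, 1, 1)).values
        assert a.equals(b)

    def test_empty_mask_all_missing_with_warning(self, part_solid_volume):
        ex = RadiomicsExtractor()
        with pytest.warns(UserWarning, match="empty mask"):
            fv = ex.extract(part_solid_volume,
                            np.zeros_like(part_solid_volume, bool), (1, 1, 1))
        assert fv.values.isna().all()
        assert fv.n_missing == 364

    def test_single_voxel_mask_texture_missing(self, part_solid_volume):
        mask = np.zeros_like(part_solid_volume, bool)
        mask[16, 16, 16] = True
        fv = RadiomicsExtractor().extract(part_solid_volume, mask, (1, 1, 1))
        assert fv.values["F1"] == part_solid_volume[16, 16, 16]  # mean
        assert np.isnan(fv.values[CATALOGUE["laws_L5L5L5"].code])
        assert fv.n_missing > 0

    def test_misaligned_inputs_rejected(self, part_solid_volume):
        with pytest.raises(ValueError, match="misaligned"):
            RadiomicsExtractor().extract(part_solid_volume,
                                         np.ones((4, 4, 4), bool), (1, 1, 1))

    def test_discretize_levels(self):
        x = np.array([0.0, 1.0, 2.0, 31.0, 32.0])
        g = discretize(x, 32)
        assert g.min() == 1 and g.max() == 32
        assert discretize(np.full(5, 3.0), 32).tolist() == [1] * 5
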