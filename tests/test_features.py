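import numpy as np
import pytest

import oracles
from radiomod.features import (
    DIRECTIONS,
    ExtractionConfig,
    FIRST_ORDER_NAMES,
    base_feature_name,
    extract_all,
    feature_bank,
    first_order,
    glcm_features,
    glcm_matrix,
    glszm_features,
    log_features,
    log_filter,
    prior_subset,
    rlgl_features,
    run_length_matrix,
    shape_features,
    size_zone_matrix,
    wavelet_bands,
    wavelet_features,
)
from radiomod.preprocess import GrayVolume, VolumeWithMask, discretize


def _vol(intensities, mask=None, spacing=(1.0, 1.0, 1.0)):
    intensities = np.asarray(intensities, dtype=float)
    if mask is None:
        mask = np.ones(intensities.shape, bool)
    return VolumeWithMask(intensities, np.asarray(mask, bool), spacing)


class TestFirstOrder:
    def test_simple_arithmetic_case(self):
        v = _vol(np.array([1.0, 2.0, 3.0]).reshape(1, 1, 3))
        f = first_order(v, bin_width=1.0)
        assert f["mean"] == 2.0
        assert f["energy"] == 14.0
        assert f["range"] == 2.0

    def test_constant_volume_degenerate_statistics(self):
        v = _vol(np.full((2, 2, 2), 9.0))
        f = first_order(v)
        assert f["entropy"] == 0.0
        assert f["variance"] == 0.0
        assert f["range"] == 0.0
        assert f["skewness"] == 0.0  # degenerate sentinel

    def test_moments_match_brute_force(self):
        vals = np.array([1.0, 1.0, 2.0, 4.0]).reshape(1, 1, 4)
        v = _vol(vals)
        f = first_order(v, bin_width=1.0)
        g = discretize(v, 1.0)
        expected = oracles.first_order_oracle(
            vals.ravel(), g.levels.ravel().tolist()
        )
        for name in FIRST_ORDER_NAMES:
            assert f[name] == pytest.approx(expected[name], abs=1e-12)

    def test_oracle_equivalence_random_volume(self, small_textured_volume):
        f = first_order(small_textured_volume, bin_width=30.0)
        g = discretize(small_textured_volume, 30.0)
        expected = oracles.first_order_oracle(
            small_textured_volume.masked_values(), g.levels[g.mask].tolist()
        )
        for name in FIRST_ORDER_NAMES:
            assert f[name] == pytest.approx(expected[name], abs=1e-9)

    def test_intensity_scaling(self, small_textured_volume):
        f1 = first_order(small_textured_volume, bin_width=25.0)
        v2 = VolumeWithMask(
            small_textured_volume.intensities * 2,
            small_textured_volume.mask,
            small_textured_volume.spacing_mm,
        )
        f2 = first_order(v2, bin_width=50.0)
        assert f2["mean"] == pytest.approx(2 * f1["mean"])
        assert f2["median"] == pytest.approx(2 * f1["median"])
        assert f2["range"] == pytest.approx(2 * f1["range"])
        assert f2["variance"] == pytest.approx(4 * f1["variance"])
        # discretization-level features unchanged when width scales too
        assert f2["entropy"] == pytest.approx(f1["entropy"])
        assert f2["uniformity"] == pytest.approx(f1["uniformity"])


class TestShape:
    def test_cube_closed_form(self):
        v = _vol(np.full((10, 10, 10), 1.0))
        f = shape_features(v)
        assert f["volume"] == pytest.approx(1000.0)
        assert f["surface_area"] == pytest.approx(600.0)
        assert f["sphericity"] == pytest.approx(
            np.pi ** (1 / 3) * (6 * 1000) ** (2 / 3) / 600, rel=1e-12
        )
        assert f["sphericity"] == pytest.approx(0.806, abs=1e-3)

    def test_single_voxel_conventions(self):
        v = _vol(np.full((1, 1, 1), 5.0))
        f = shape_features(v)
        assert f["volume"] == pytest.approx(1.0)
        assert f["maximum_3d_diameter"] == 0.0

    def test_sphericity_bounded_by_one(self, noise_sphere):
        f = shape_features(noise_sphere)
        assert f["sphericity"] <= 1.0 + 1e-9

    def test_oracle_equivalence(self, small_textured_volume):
        f = shape_features(small_textured_volume)
        exp = oracles.shape_oracle(
            small_textured_volume.mask, small_textured_volume.spacing_mm
        )
        for name, value in exp.items():
            assert f[name] == pytest.approx(value, abs=1e-9), name

    def test_anisotropic_spacing_in_physical_units(self):
        mask = np.ones((2, 3, 4), bool)
        v = _vol(np.zeros((2, 3, 4)), mask, spacing=(2.0, 1.0, 0.5))
        f = shape_features(v)
        exp = oracles.shape_oracle(mask, (2.0, 1.0, 0.5))
        assert f["volume"] == pytest.approx(exp["volume"])
        assert f["surface_area"] == pytest.approx(exp["surface_area"])
        assert f["maximum_3d_diameter"] == pytest.approx(exp["maximum_3d_diameter"])


class TestGLCM:
    def test_tiny_grid_matches_pair_enumeration(self):
        levels = np.array([[[1, 1], [1, 2]]])
        g = GrayVolume(levels, 2, 1.0, np.ones((1, 2, 2), bool))
        f = glcm_features(g)
        per_direction = []
        for off in DIRECTIONS:
            p = oracles.glcm_matrix_oracle(levels, g.mask, off, 2)
            if p.sum() > 0:
                per_direction.append(oracles.glcm_features_oracle(p))
        expected = {
            k: np.mean([d[k] for d in per_direction]) for k in per_direction[0]
        }
        for name, value in expected.items():
            assert f[name] == pytest.approx(value, abs=1e-9), name

    def test_constant_volume_degenerate(self):
        g = GrayVolume(np.ones((2, 2, 2), int), 1, 1.0, np.ones((2, 2, 2), bool))
        f = glcm_features(g)
        assert f["contrast"] == 0.0
        assert f["correlation"] == 0.0  # sentinel for undefined

    def test_oracle_equivalence_random_volume(self, small_gray):
        f = glcm_features(small_gray)
        per_direction = []
        for off in DIRECTIONS:
            p = oracles.glcm_matrix_oracle(
                small_gray.levels, small_gray.mask, off, small_gray.n_levels
            )
            if p.sum() > 0:
                per_direction.append(oracles.glcm_features_oracle(p))
        for name in f.index:
            expected = np.mean([d[name] for d in per_direction])
            assert f[name] == pytest.approx(expected, abs=1e-9), name

    def test_entropy_invariant_under_label_permutation(self, small_gray):
        f1 = glcm_features(small_gray)
        rng = np.random.default_rng(3)
        perm = rng.permutation(small_gray.n_levels) + 1
        relabeled = np.zeros_like(small_gray.levels)
        relabeled[small_gray.mask] = perm[small_gray.levels[small_gray.mask] - 1]
        g2 = GrayVolume(relabeled, small_gray.n_levels, 1.0, small_gray.mask)
        f2 = glcm_features(g2)
        assert f2["entropy"] == pytest.approx(f1["entropy"], abs=1e-9)
        assert f2["energy"] == pytest.approx(f1["energy"], abs=1e-9)

    def test_symmetry_of_cooccurrence_matrix(self, small_gray):
        for off in DIRECTIONS[:4]:
            p = glcm_matrix(small_gray, off)
            assert np.allclose(p, p.T)


class TestRLGL:
    def test_line_volume_single_run(self):
        n = 6
        levels = np.ones((1, 1, n), dtype=int)
        g = GrayVolume(levels, 1, 1.0, np.ones((1, 1, n), bool))
        counts = run_length_matrix(g, (0, 0, 1))
        assert counts.shape == (1, n)
        assert counts[0, n - 1] == 1  # one run of length n
        assert counts.sum() == 1
        # run percentage for that direction is 1/n
        assert counts.sum() / g.mask.sum() == pytest.approx(1 / n)

    def test_alternating_levels_all_unit_runs(self):
        levels = np.array([[[1, 2, 1, 2]]])
        g = GrayVolume(levels, 2, 1.0, np.ones((1, 1, 4), bool))
        f = rlgl_features(g)
        assert f["short_run_emphasis"] == pytest.approx(1.0)

    def test_conservation_identity_every_direction(self, small_gray):
        n_vox = int(small_gray.mask.sum())
        lengths_weighted = 0
        for off in DIRECTIONS:
            counts = run_length_matrix(small_gray, off)
            l = np.arange(1, counts.shape[1] + 1)
            assert (counts * l).sum() == n_vox  # exact
            lengths_weighted += 1
        assert lengths_weighted == 13

    def test_oracle_equivalence_random_volume(self, small_gray):
        f = rlgl_features(small_gray)
        n_vox = int(small_gray.mask.sum())
        per_dir = []
        for off in DIRECTIONS:
            runs = oracles.runs_oracle(small_gray.levels, small_gray.mask, off)
            per_dir.append(oracles.rlgl_features_oracle(runs, n_vox))
        for name in f.index:
            expected = np.mean([d[name] for d in per_dir])
            assert f[name] == pytest.approx(expected, abs=1e-9), name


class TestGLSZM:
    def test_constant_volume_single_zone(self):
        n = 8
        levels = np.ones((2, 2, 2), dtype=int)
        g = GrayVolume(levels, 1, 1.0, np.ones((2, 2, 2), bool))
        counts = size_zone_matrix(g)
        assert counts[0, n - 1] == 1 and counts.sum() == 1
        f = glszm_features(g)
        assert f["zone_percentage"] == pytest.approx(1 / n)

    def test_bridging_voxel_merges_zones(self):
        levels = np.zeros((1, 1, 5), dtype=int)
        mask = np.zeros((1, 1, 5), bool)
        levels[0, 0, [0, 1]] = 1
        levels[0, 0, [3, 4]] = 1
        mask[0, 0, [0, 1, 3, 4]] = True
        g = GrayVolume(levels, 1, 1.0, mask)
        assert size_zone_matrix(g).sum() == 2  # two disjoint zones
        levels[0, 0, 2] = 1
        mask[0, 0, 2] = True
        g2 = GrayVolume(levels, 1, 1.0, mask)
        counts = size_zone_matrix(g2)
        assert counts.sum() == 1  # bridged into one zone
        assert counts[0, 4] == 1

    def test_conservation_identity(self, small_gray):
        counts = size_zone_matrix(small_gray)
        s = np.arange(1, counts.shape[1] + 1)
        assert (counts * s).sum() == small_gray.mask.sum()

    def test_oracle_equivalence_random_volume(self, small_gray):
        f = glszm_features(small_gray)
        zones = oracles.zones_oracle(small_gray.levels, small_gray.mask)
        expected = oracles.glszm_features_oracle(
            zones, int(small_gray.mask.sum())
        )
        for name, value in expected.items():
            assert f[name] == pytest.approx(value, abs=1e-9), name


class TestWaveletAndLoG:
    def test_constant_volume_detail_bands_vanish(self):
        arr = np.full((6, 6, 6), 40.0)
        bands = wavelet_bands(arr, "coif1")
        assert len(bands) == 8
        for label, band in bands.items():
            if label == "LLL":
                assert np.allclose(band, band.flat[0])
                assert abs(band.flat[0]) > 0
            else:
                assert np.allclose(band, 0.0, atol=1e-8)

    def test_impulse_matches_direct_separable_convolution(self):
        import pywt
        from scipy.ndimage import convolve1d

        arr = np.zeros((8, 8, 8))
        arr[4, 4, 4] = 1.0
        bands = wavelet_bands(arr, "coif1")
        w = pywt.Wavelet("coif1")
        lo = np.array(w.dec_lo)
        hi = np.array(w.dec_hi)
        # the stationary transform correlates each axis with the periodized
        # high-pass filter (empirically pinned convention in 1D)
        out = arr.copy()
        for axis in range(3):
            out = convolve1d(out, hi, axis=axis, mode="wrap")
        assert np.abs(out - bands["HHH"]).max() < 1e-8
        out_l = arr.copy()
        for axis in range(3):
            out_l = convolve1d(out_l, lo, axis=axis, mode="wrap")
        assert np.abs(out_l - bands["LLL"]).max() < 1e-8

    def test_wavelet_feature_names_carry_band(self, noise_sphere):
        f = wavelet_features(noise_sphere)
        assert len(f) == 8 * (14 + 23 + 11)
        assert any(name.startswith("wavelet_HHH_") for name in f.index)

    def test_log_constant_and_ramp_respond_zero(self):
        # responses vanish up to the truncation error of the discrete kernel
        v = _vol(np.full((9, 9, 9), 30.0))
        f = log_features(v, sigmas_mm=[1.0])
        assert f["log_sigma_1_0_mm_firstorder_mean"] == pytest.approx(0.0, abs=0.03)

        x = np.arange(15, dtype=float)
        ramp = np.broadcast_to(x, (15, 15, 15)).copy()
        inner = np.zeros((15, 15, 15), bool)
        inner[5:10, 5:10, 5:10] = True  # away from boundary effects
        v = _vol(ramp, inner)
        resp = log_filter(v, 1.0)
        assert np.abs(resp[inner]).max() < 0.01 * ramp.max()

    def test_log_sigma_must_be_positive(self, noise_sphere):
        with pytest.raises(ValueError):
            log_features(noise_sphere, sigmas_mm=[-1.0])

    def test_log_matches_direct_convolution_on_blob(self):
        from scipy import ndimage

        rng = np.random.default_rng(5)
        arr = rng.standard_normal((12, 12, 12))
        v = _vol(arr)
        resp = log_filter(v, 2.0)
        expected = ndimage.gaussian_laplace(arr, sigma=[2.0, 2.0, 2.0])
        assert np.allclose(resp, expected, atol=1e-9)


class TestBankContract:
    def test_bank_enumerates_636_with_440_prior_subset(self):
        assert len(feature_bank()) == 636
        assert len(prior_subset()) == 440
        assert len(set(feature_bank())) == 636  # names unique

    def test_extract_all_produces_full_bank(self, noise_sphere):
        vec = extract_all(noise_sphere)
        assert len(vec) == 636
        assert not vec.isna().any()
        assert vec.attrs["config_hash"] == ExtractionConfig().config_hash()

    def test_extraction_is_deterministic(self, noise_sphere):
        v1 = extract_all(noise_sphere)
        v2 = extract_all(noise_sphere)
        assert np.array_equal(v1.to_numpy(), v2.to_numpy())

    def test_translation_invariance(self, small_textured_volume):
        cfg = ExtractionConfig(resample=False, log_sigmas_mm=(1.0,))
        v = small_textured_volume
        vec1 = extract_all(v, cfg)
        padded_int = np.pad(v.intensities, ((2, 0), (1, 0), (3, 0)))
        padded_mask = np.pad(v.mask, ((2, 0), (1, 0), (3, 0)))
        v2 = VolumeWithMask(padded_int, padded_mask, v.spacing_mm)
        vec2 = extract_all(v2, cfg)
        # LoG and wavelet see the padded zeros only outside the mask; shape,
        # first-order and texture features are exactly translation invariant
        exact = [n for n in vec1.index if n.startswith("original_")]
        assert np.allclose(vec1[exact], vec2[exact], atol=1e-9)

    def test_rotation_invariance_of_direction_averaged_texture(self, small_gray):
        f1 = glcm_features(small_gray)
        r1 = rlgl_features(small_gray)
        rot_levels = np.rot90(small_gray.levels, k=1, axes=(1, 2))
        rot_mask = np.rot90(small_gray.mask, k=1, axes=(1, 2))
        g2 = GrayVolume(rot_levels, small_gray.n_levels, 1.0, rot_mask)
        f2 = glcm_features(g2)
        r2 = rlgl_features(g2)
        assert np.allclose(f1.to_numpy(), f2.to_numpy(), atol=1e-9)
        assert np.allclose(r1.to_numpy(), r2.to_numpy(), atol=1e-9)

    def test_base_name_collapse(self):
        assert base_feature_name("wavelet_HHH_glcm_entropy") == "glcm_entropy"
        assert base_feature_name("log_sigma_2_5_mm_firstorder_mean") == "firstorder_mean"
        assert base_feature_name("original_shape_volume") == "shape_volume"
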