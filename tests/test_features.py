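"""Feature panel: discretization contract, family-wise brute-force oracle
equivalence, degenerate-lesion conventions, and invariance properties."""

import numpy as np
import pytest

from dtpradiomics.config import PipelineConfig
from dtpradiomics.features import (
    DIRECTIONS_13,
    FEATURE_NAMES,
    bin_index,
    extract_features,
    glcm_features,
    glrlm_features,
    glrlm_matrix,
    glzlm_features,
    glzlm_matrix,
    histogram_features,
    ngldm_features,
    preprocess,
    shape_features,
)
from dtpradiomics.features.intensity import conventional_indices
from dtpradiomics.segmentation import VOI
from dtpradiomics.volumes import ImageVolume, UnitTag

from conftest import make_disc
from oracles import (
    glcm_features_bruteforce,
    glrlm_counts_bruteforce,
    glzlm_counts_bruteforce,
    ngldm_features_bruteforce,
)


class TestDiscretization:
    def test_printed_configuration_contract(self, cfg):
        # 64 bins over [0, 20]: bin(0)=1, bin(20)=64, bin(10)=33, width 0.3125
        assert bin_index(0.0, 64, 0, 20) == 1
        assert bin_index(20.0, 64, 0, 20) == 64
        assert bin_index(10.0, 64, 0, 20) == 33
        assert (cfg.intensity_max - cfg.intensity_min) / cfg.bin_count == 0.3125

    def test_out_of_window_values_clamped(self):
        assert bin_index(-3.0, 64, 0, 20) == 1   # negative scaled-Ki voxels
        assert bin_index(25.0, 64, 0, 20) == 64

    def test_constant_lesion_single_level(self, cfg):
        vol = ImageVolume(np.full((6, 6, 6), 5.0), spacing=(4, 4, 4))
        mask = np.zeros((6, 6, 6), bool)
        mask[2:5, 2:5, 2:5] = True
        d = preprocess(vol, VOI(mask=mask), cfg)
        assert set(np.unique(d.level_values())) == {bin_index(5.0, 64, 0, 20)}

    def test_absolute_bounds_shift_changes_levels(self, cfg):
        rng = np.random.default_rng(0)
        data = rng.uniform(2, 10, (6, 6, 6))
        mask = np.ones((6, 6, 6), bool)
        d0 = preprocess(ImageVolume(data, spacing=(4, 4, 4)), VOI(mask=mask), cfg)
        d1 = preprocess(ImageVolume(data + 1.0, spacing=(4, 4, 4)), VOI(mask=mask), cfg)
        assert not np.array_equal(d0.levels, d1.levels)

    def test_wrong_unit_tag_rejected(self, cfg):
        vol = ImageVolume(np.ones((4, 4, 4)), spacing=(4, 4, 4), unit_tag=UnitTag.KI_RAW)
        with pytest.raises(ValueError, match="SUV or KI_SCALED"):
            preprocess(vol, VOI(mask=np.ones((4, 4, 4), bool)), cfg)


class TestGlcm:
    def test_constant_lesion_degenerate_values(self):
        d = make_disc(np.full((3, 3, 3), 2, dtype=int))
        f = glcm_features(d)
        assert f["Energy"] == 1.0
        assert f["Entropy"] == 0.0
        assert f["Contrast"] == 0.0
        assert f["Homogeneity"] == 1.0
        assert f["Dissimilarity"] == 0.0
        assert f["Correlation"] == 1.0

    def test_strip_single_direction_vs_hand_enumeration(self):
        # 1D strip [1,2,1,2] along x, pairs counted both ways:
        # (1,2)x3, (2,1)x3 -> p offdiag 0.5/0.5
        levels = np.zeros((4, 1, 1), int)
        levels[:, 0, 0] = [1, 2, 1, 2]
        d = make_disc(levels, bin_count=2)
        f = glcm_features(d, directions=((1, 0, 0),))
        assert f["Energy"] == pytest.approx(0.5)
        assert f["Contrast"] == pytest.approx(1.0)
        assert f["Dissimilarity"] == pytest.approx(1.0)
        assert f["Homogeneity"] == pytest.approx(0.5)
        assert f["Entropy"] == pytest.approx(np.log(2))
        assert f["Correlation"] == pytest.approx(-1.0)

    def test_entropy_log2_is_base_change(self, random_lesion):
        f = glcm_features(random_lesion(11))
        assert f["Entropy_log2"] == pytest.approx(f["Entropy"] / np.log(2))

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bruteforce(self, seed, random_lesion):
        d = random_lesion(seed)
        ours = glcm_features(d)
        ref = glcm_features_bruteforce(d.levels, d.mask, d.bin_count, DIRECTIONS_13)
        for k in ours:
            assert ours[k] == pytest.approx(ref[k], rel=1e-10, abs=1e-12), k


class TestNgldm:
    def test_constant_lesion(self):
        d = make_disc(np.full((3, 3, 3), 3, dtype=int))
        f = ngldm_features(d)
        assert f["Contrast"] == 0.0
        assert f["Busyness"] == 0.0
        assert f["Coarseness"] == 1e6  # capped

    def test_small_patch_matches_bruteforce(self):
        levels = np.zeros((2, 2, 1), int)
        levels[:, :, 0] = [[1, 1], [1, 2]]
        d = make_disc(levels, bin_count=2)
        ours = ngldm_features(d)
        ref = ngldm_features_bruteforce(d.levels, d.mask, d.bin_count)
        for k in ours:
            assert ours[k] == pytest.approx(ref[k], rel=1e-10), k

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bruteforce_random(self, seed, random_lesion):
        d = random_lesion(100 + seed)
        ours = ngldm_features(d)
        ref = ngldm_features_bruteforce(d.levels, d.mask, d.bin_count)
        for k in ours:
            assert ours[k] == pytest.approx(ref[k], rel=1e-10), k

    def test_texture_scale_and_amplitude_monotonicity(self):
        """Finer synthetic texture lowers coarseness; larger amplitude raises
        neighborhood contrast (averaged over seeds)."""
        from dtpradiomics.synthetic import LesionSpec, PhantomSpec, simulate_dtp_study
        from dtpradiomics.input_function import DEFAULT_POPULATION_IF
        from dtpradiomics.kinetics import TimePair, compute_ki_map

        def run(amp, corr_mm):
            vals = []
            for seed in range(5):
                spec = PhantomSpec(lesions=[LesionSpec(
                    center_mm=(64, 64, 64), radius_mm=14, mean_ki=0.04,
                    texture_corr_mm=corr_mm, texture_amp=amp)])
                study = simulate_dtp_study(spec, DEFAULT_POPULATION_IF, 61, 133, seed=seed)
                ki = compute_ki_map(study["suv_t1"], study["act_t2"],
                                    DEFAULT_POPULATION_IF, TimePair(61, 133))
                d = preprocess(ki, VOI(mask=study["masks"][0]), PipelineConfig())
                f = ngldm_features(d)
                vals.append((f["Coarseness"], f["Contrast"]))
            return np.mean(vals, axis=0)

        fine, coarse = run(0.01, 3.0), run(0.01, 12.0)
        assert fine[0] < coarse[0]
        small, big = run(0.004, 6.0), run(0.02, 6.0)
        assert small[1] < big[1]


class TestGlrlm:
    def test_strip_hand_enumeration(self):
        # [1,1,2,2,2] one direction: runs {(1,len2),(2,len3)}
        levels = np.zeros((5, 1, 1), int)
        levels[:, 0, 0] = [1, 1, 2, 2, 2]
        d = make_disc(levels, bin_count=2)
        f = glrlm_features(d, directions=((1, 0, 0),))
        assert f["RLNU"] == pytest.approx(1.0)
        assert f["GLNU"] == pytest.approx(1.0)
        assert f["SRE"] == pytest.approx((1 / 4 + 1 / 9) / 2)
        assert f["RP"] == pytest.approx(2 / 5)

    def test_constant_strip_single_run(self):
        n = 7
        levels = np.full((n, 1, 1), 3, dtype=int)
        d = make_disc(levels, bin_count=4)
        f = glrlm_features(d, directions=((1, 0, 0),))
        assert f["RP"] == pytest.approx(1 / n)
        assert f["LRE"] == pytest.approx(n**2)

    @pytest.mark.parametrize("seed", range(12))
    def test_matrix_matches_line_splitting_oracle(self, seed, random_lesion):
        d = random_lesion(200 + seed)
        ours = glrlm_matrix(d.levels, d.mask, d.bin_count, DIRECTIONS_13)
        ref = glrlm_counts_bruteforce(d.levels, d.mask, d.bin_count, DIRECTIONS_13)
        np.testing.assert_allclose(ours[:, : ref.shape[1]], ref)
        assert ours[:, ref.shape[1]:].sum() == 0

    def test_aggregate_equals_sum_of_directions(self, random_lesion):
        d = random_lesion(42)
        total = glrlm_matrix(d.levels, d.mask, d.bin_count, DIRECTIONS_13)
        per_dir = sum(
            glrlm_matrix(d.levels, d.mask, d.bin_count, (dd,)) for dd in DIRECTIONS_13
        )
        np.testing.assert_allclose(total, per_dir)


class TestGlzlm:
    def test_constant_lesion_single_zone(self):
        levels = np.zeros((4, 4, 4), int)
        levels[1:3, 1:3, 1:3] = 2
        d = make_disc(levels, bin_count=3)
        n = 8
        f = glzlm_features(d)
        assert f["ZP"] == pytest.approx(1 / n)
        assert f["LZE"] == pytest.approx(n**2)

    def test_checkerboard_zone_structure(self):
        # 2x2x1 checkerboard: under 26-connectivity the two diagonal voxels
        # of each level touch, giving two zones of size 2
        levels = np.zeros((2, 2, 1), int)
        levels[:, :, 0] = [[1, 2], [2, 1]]
        d = make_disc(levels, bin_count=2)
        f = glzlm_features(d)
        assert f["SZE"] == pytest.approx(0.25)
        assert f["ZP"] == pytest.approx(0.5)

    def test_face_checkerboard_singleton_zones(self):
        # separate same-level voxels beyond the 26-neighborhood: all singletons
        levels = np.zeros((3, 3, 1), int)
        levels[:, :, 0] = [[1, 0, 1], [0, 0, 0], [1, 0, 1]]
        d = make_disc(levels, bin_count=2)
        f = glzlm_features(d)
        assert f["SZE"] == pytest.approx(1.0)
        assert f["ZP"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(12))
    def test_zones_match_flood_fill_oracle(self, seed, random_lesion):
        d = random_lesion(300 + seed, shape=(5, 5, 5))
        ours = glzlm_matrix(d.levels, d.mask, d.bin_count)
        ref = glzlm_counts_bruteforce(d.levels, d.mask, d.bin_count)
        np.testing.assert_allclose(ours[:, : ref.shape[1]], ref)
        assert ours[:, ref.shape[1]:].sum() == 0


class TestShape:
    def test_cube_surface_and_volume(self):
        mask = np.zeros((12, 12, 12), bool)
        mask[1:11, 1:11, 1:11] = True
        f = shape_features(mask, (4, 4, 4))
        assert f["Volume_vx"] == 1000
        assert f["Volume_mL"] == pytest.approx(64.0)
        assert f["Surface_mm2"] == pytest.approx(9600.0)
        assert f["Sphericity"] == pytest.approx(np.pi ** (1 / 3) * 6 ** (2 / 3) / 6, rel=1e-12)

    def test_digital_ball_sphericity_near_one(self):
        from dtpradiomics.volumes import sphere_mask

        # the face-counted (staircase) surface of a ball converges to 1.5x
        # the smooth sphere area, so voxel sphericity of a ball tends to 2/3
        mask = sphere_mask((40, 40, 40), (2, 2, 2), (0, 0, 0), (40, 40, 40), 24)
        f = shape_features(mask, (2, 2, 2))
        assert 0.6 < f["Sphericity"] < 0.75
        r, v = 24.0, f["Volume_mL"] * 1000
        assert f["Surface_mm2"] == pytest.approx(1.5 * 4 * np.pi * r**2, rel=0.05)

    def test_compacity_definition(self):
        mask = np.ones((2, 2, 2), bool)
        f = shape_features(mask, (1, 1, 1))
        v, s = 8.0, 24.0
        assert f["Compacity"] == pytest.approx(v / (np.sqrt(np.pi) * s**1.5))


class TestHistogram:
    def test_constant_lesion(self):
        d = make_disc(np.full((3, 3, 3), 4, dtype=int))
        f = histogram_features(d)
        assert f["Uniformity"] == 1.0
        assert f["Entropy"] == 0.0
        assert f["AUC_CSH"] == pytest.approx(1.0)

    def test_two_equal_bins(self):
        levels = np.zeros((4, 1, 1), int)
        levels[:, 0, 0] = [1, 1, 2, 2]
        f = histogram_features(make_disc(levels, bin_count=2))
        assert f["Uniformity"] == pytest.approx(0.5)
        assert f["Entropy_log2"] == pytest.approx(1.0)

    def test_auc_csh_step_function_oracle(self):
        # values {2, 4}: frac(x)=1 for x<=0.5, 0.5 for x in (0.5, 1]
        # integral = 0.5*1 + 0.5*0.5 = 0.75
        levels = np.zeros((2, 1, 1), int)
        levels[:, 0, 0] = [1, 2]
        cont = np.zeros((2, 1, 1))
        cont[:, 0, 0] = [2.0, 4.0]
        d = make_disc(levels, bin_count=2, continuous=cont)
        assert histogram_features(d)["AUC_CSH"] == pytest.approx(0.75, abs=1e-3)

    def test_adding_occupied_bin_lowers_uniformity(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n_bins = rng.integers(2, 6)
            counts = rng.integers(1, 10, n_bins)
            vals = np.repeat(np.arange(1, n_bins + 1), counts)
            levels = np.zeros((vals.size, 1, 1), int)
            levels[:, 0, 0] = vals
            u_before = histogram_features(make_disc(levels, bin_count=n_bins + 1))["Uniformity"]
            # move one voxel into a previously empty bin
            levels2 = levels.copy()
            levels2[0, 0, 0] = n_bins + 1
            u_after = histogram_features(make_disc(levels2, bin_count=n_bins + 1))["Uniformity"]
            assert u_after <= u_before + 1e-12


class TestConventional:
    def test_constant_lesion(self):
        vals = np.full((10, 10, 10), 5.0)
        mask = np.ones((10, 10, 10), bool)
        f = conventional_indices(vals, mask, (4, 4, 4), volume_ml=64.0)
        assert f["mean"] == 5.0
        assert f["std"] == 0.0
        assert f["TLG_mL"] == pytest.approx(320.0)
        assert f["Skewness"] == 0.0 and f["Kurtosis"] == 0.0

    def test_quantiles_linear_interpolation(self):
        vals = np.arange(1.0, 101.0).reshape((100, 1, 1))
        mask = np.ones((100, 1, 1), bool)
        f = conventional_indices(vals, mask, (4, 4, 4), volume_ml=6.4)
        assert f["Q1"] == pytest.approx(25.75)
        assert f["Q2"] == pytest.approx(50.5)
        assert f["Q3"] == pytest.approx(75.25)

    def test_gaussian_excess_kurtosis_near_zero(self):
        rng = np.random.default_rng(10)
        vals = rng.standard_normal((47, 47, 47))  # ~1e5 voxels
        mask = np.ones(vals.shape, bool)
        f = conventional_indices(vals, mask, (4, 4, 4), volume_ml=1.0)
        assert abs(f["ExcessKurtosis"]) < 0.05
        assert f["Kurtosis"] == pytest.approx(f["ExcessKurtosis"] + 3.0)

    def test_peak_is_mean_over_half_ml_sphere(self):
        vals = np.zeros((9, 9, 9))
        vals[4, 4, 4] = 10.0
        mask = np.ones((9, 9, 9), bool)
        f = conventional_indices(vals, mask, (4, 4, 4), volume_ml=46.656)
        # 0.5 mL sphere at 4 mm spacing: center + 6 face neighbors = 7 voxels
        assert f["peak"] == pytest.approx(10.0 / 7.0)


class TestExtractAll:
    def _lesion_volume(self, seed=0, shape=(10, 10, 10)):
        rng = np.random.default_rng(seed)
        data = rng.uniform(1, 12, shape)
        mask = np.zeros(shape, bool)
        mask[3:8, 3:8, 3:8] = True
        return ImageVolume(data, spacing=(4, 4, 4)), VOI(mask=mask)

    def test_panel_has_65_finite_features_in_canonical_order(self, cfg):
        vol, voi = self._lesion_volume()
        vec = extract_features(vol, voi, cfg)
        assert tuple(vec.index) == FEATURE_NAMES
        assert len(vec) == 65
        assert np.isfinite(vec.to_numpy()).all()

    def test_identical_inputs_identical_vectors(self, cfg):
        from dtpradiomics.features import extract_all

        vol, voi = self._lesion_volume(3)
        ki = vol.with_data(vol.data.copy(), unit_tag=UnitTag.KI_SCALED)
        static, dtp = extract_all(vol, ki, voi, VOI(mask=voi.mask.copy()), cfg)
        np.testing.assert_array_equal(static.to_numpy(), dtp.to_numpy())

    def test_translation_invariance(self, cfg):
        rng = np.random.default_rng(9)
        patch = rng.uniform(1, 12, (5, 5, 5))
        vecs = []
        for offset in ((1, 1, 1), (3, 2, 4)):
            data = np.zeros((12, 12, 12))
            sl = tuple(slice(o, o + 5) for o in offset)
            data[sl] = patch
            mask = np.zeros((12, 12, 12), bool)
            mask[sl] = True
            vecs.append(extract_features(ImageVolume(data, spacing=(4, 4, 4)), VOI(mask=mask), cfg))
        np.testing.assert_allclose(vecs[0].to_numpy(), vecs[1].to_numpy(), rtol=1e-12)

    def test_rotation_invariance(self, cfg):
        rng = np.random.default_rng(13)
        data = np.zeros((10, 10, 10))
        mask = np.zeros((10, 10, 10), bool)
        data[2:8, 2:7, 3:8] = rng.uniform(1, 12, (6, 5, 5))
        mask[2:8, 2:7, 3:8] = True
        v0 = extract_features(ImageVolume(data, spacing=(4, 4, 4)), VOI(mask=mask), cfg)
        v1 = extract_features(
            ImageVolume(np.rot90(data, axes=(0, 1)).copy(), spacing=(4, 4, 4)),
            VOI(mask=np.rot90(mask, axes=(0, 1)).copy()),
            cfg,
        )
        np.testing.assert_allclose(v0.to_numpy(), v1.to_numpy(), rtol=1e-10)

    @pytest.mark.parametrize("seed", range(25))
    def test_fuzz_always_finite(self, seed, cfg):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(6, 12, 3))
        data = rng.uniform(-2, 25, shape)  # includes out-of-window values
        mask = rng.random(shape) < 0.4
        if not mask.any():
            mask[0, 0, 0] = True
        vec = extract_features(ImageVolume(data, spacing=(4, 4, 4)), VOI(mask=mask), cfg)
        assert np.isfinite(vec.to_numpy()).all()
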