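import numpy as np
import pytest

from cervitex.texture import (
    FeatureConfig,
    GLRLM_ORIENTATIONS,
    assemble_features,
    eltp_code,
    eltp_descriptor,
    glrlm,
    glrlm_features,
    moment_invariants,
    quantize_gray,
)
from conftest import brute_force_glrlm_features, brute_force_runs


class TestGlrlm:
    def test_worked_example_0deg(self, fixtures):
        fx = fixtures["glrlm_4x4"]
        M = glrlm(fx["image"], 0, fx["gray_bins"], fx["levels"])
        for (a, b), count in fx["expected_runs_0deg"].items():
            assert M.counts[a, b - 1] == count
        assert M.num_runs == fx["num_runs_0deg"]

    def test_worked_example_90deg(self, fixtures):
        fx = fixtures["glrlm_4x4"]
        M = glrlm(fx["image"], 90, fx["gray_bins"], fx["levels"])
        b = np.arange(1, M.counts.shape[1] + 1)
        assert np.sum(M.counts * b) == 16  # pixel conservation
        # every column is two 2-runs then runs of 1: lengths (2,1,1) per column
        assert M.counts[:, 1].sum() == 4  # four 2-runs (columns x upper half)

    def test_constant_image(self):
        M = glrlm(np.full((5, 5), 3), 0, gray_bins=8, levels=8)
        assert M.counts[3, 4] == 5  # five rows, each one maximal 5-run
        assert M.num_runs == 5

    @pytest.mark.parametrize("orientation", GLRLM_ORIENTATIONS)
    def test_pixel_conservation_random(self, orientation, rng):
        for _ in range(5):
            img = rng.integers(0, 256, (13, 9))
            M = glrlm(img, orientation, gray_bins=8)
            b = np.arange(1, M.counts.shape[1] + 1)
            assert np.sum(M.counts * b) == img.size
            assert M.num_runs == M.counts.sum()

    @pytest.mark.parametrize("orientation", GLRLM_ORIENTATIONS)
    def test_matches_brute_force_runs(self, orientation, rng):
        img = rng.integers(0, 4, (6, 7))
        M = glrlm(img, orientation, gray_bins=4, levels=4)
        expected = brute_force_runs(np.asarray(img), orientation)
        got = {
            (a, b + 1): int(M.counts[a, b])
            for a, b in zip(*np.nonzero(M.counts))
        }
        assert got == expected

    def test_bad_orientation(self):
        with pytest.raises(ValueError, match="orientation"):
            glrlm(np.zeros((3, 3), dtype=int), 30)

    def test_quantization(self):
        img = np.array([[0, 64, 128, 255]])
        assert quantize_gray(img, 4).tolist() == [[0, 1, 2, 3]]


class TestGlrlmFeatures:
    def test_worked_values(self, fixtures):
        fx = fixtures["glrlm_4x4"]
        feats = glrlm_features(glrlm(fx["image"], 0, fx["gray_bins"], fx["levels"]))
        assert feats[0] == pytest.approx(fx["SHE_0deg"])
        assert feats[2] == pytest.approx(fx["GLNU_0deg"])

    def test_single_run_limit(self):
        M = glrlm(np.full((1, 6), 2), 0, gray_bins=4, levels=4)
        feats = glrlm_features(M)
        assert M.num_runs == 1
        assert feats[4] == pytest.approx(1 / 6)  # RUP = 1/Npixels
        assert feats[0] == pytest.approx(1 / 36)  # SHE = 1/b^2

    def test_matches_brute_force(self, rng):
        for orientation in GLRLM_ORIENTATIONS:
            img = rng.integers(0, 3, (5, 5))
            M = glrlm(img, orientation, gray_bins=3, levels=3)
            expected = brute_force_glrlm_features(
                brute_force_runs(np.asarray(img), orientation), img.size
            )
            assert np.allclose(glrlm_features(M), expected)

    def test_invariant_bounds(self, rng):
        img = rng.integers(0, 256, (16, 16))
        feats = glrlm_features(glrlm(img, 0))
        assert (feats >= 0).all()
        assert 0 < feats[4] <= 1  # run percentage

    def test_empty_matrix_rejected(self):
        from cervitex.texture import RunLengthMatrix

        with pytest.raises(ValueError, match="empty"):
            glrlm_features(RunLengthMatrix(np.zeros((2, 2), dtype=int), 0, 2, 4))


class TestEltpCode:
    def test_worked_example(self, fixtures):
        fx = fixtures["eltp_patch"]
        codes = eltp_code(fx["neighbors"], fx["ace"], fx["we"])
        assert np.array_equal(codes, fx["expected_codes"])

    def test_constant_patch_codes_zero(self):
        codes = eltp_code(np.full(8, 5.0), ace=5.0, we=0.0)
        assert np.array_equal(codes, np.zeros(8))

    def test_boundary_inclusive(self):
        # neighbor exactly at ace + we codes +1
        codes = eltp_code(np.array([7.0, 6.0, 5.0, 3.0]), ace=5.0, we=2.0)
        assert codes.tolist() == [1, 0, 0, -1]

    def test_too_few_neighbors(self):
        with pytest.raises(ValueError):
            eltp_code(np.array([1.0, 2.0]), 1.0, 1.0)


class TestEltpDescriptor:
    def test_constant_image_all_zero_codes(self):
        desc = eltp_descriptor(np.full((8, 8), 100))
        assert desc.upper_hist[0] == desc.n_coded  # all-zeros bin is bin 0
        assert desc.lower_hist[0] == desc.n_coded

    def test_histograms_sum_to_coded_pixels(self, rng):
        img = rng.integers(0, 256, (10, 12))
        desc = eltp_descriptor(img)
        assert desc.upper_hist.sum() == desc.lower_hist.sum() == 8 * 10

    @pytest.mark.parametrize("turns", [1, 2, 3])
    def test_rotation_invariance(self, turns, rng):
        img = rng.integers(0, 256, (12, 12))
        a = eltp_descriptor(img, rotation_invariant=True)
        b = eltp_descriptor(np.rot90(img, turns), rotation_invariant=True)
        assert np.array_equal(a.upper_hist, b.upper_hist)
        assert np.array_equal(a.lower_hist, b.lower_hist)

    def test_inversion_swaps_channels(self, rng):
        img = rng.integers(0, 256, (11, 13))
        a = eltp_descriptor(img)
        b = eltp_descriptor(255 - img)
        assert np.array_equal(a.upper_hist, b.lower_hist)
        assert np.array_equal(a.lower_hist, b.upper_hist)

    def test_radius_too_large(self):
        with pytest.raises(ValueError, match="too small"):
            eltp_descriptor(np.zeros((4, 4), dtype=int), R=2)

    def test_non_ri_bins(self, rng):
        img = rng.integers(0, 256, (8, 8))
        desc = eltp_descriptor(img, rotation_invariant=False)
        assert desc.upper_hist.size == 256


class TestMomentInvariants:
    def test_translation_invariance_exact(self, rng):
        img = np.zeros((32, 32))
        img[4:12, 6:16] = rng.random((8, 10))
        shifted = np.roll(np.roll(img, 9, axis=0), 5, axis=1)
        a, b = moment_invariants(img), moment_invariants(shifted)
        assert np.allclose(a.central_moments, b.central_moments, atol=1e-9)
        assert np.allclose(a.hu, b.hu, atol=1e-12)

    def test_rotation_invariance(self, rng):
        img = rng.random((32, 32))
        a = moment_invariants(img)
        b = moment_invariants(np.rot90(img))
        assert np.allclose(a.hu, b.hu, atol=1e-6)

    def test_central_by_construction(self, rng):
        img = rng.random((16, 16))
        mi = moment_invariants(img)
        assert mi.central_moments[0, 0] == pytest.approx(img.sum())
        assert abs(mi.central_moments[1, 0]) < 1e-9
        assert abs(mi.central_moments[0, 1]) < 1e-9

    def test_symmetric_square_odd_moments_vanish(self):
        img = np.zeros((15, 15))
        img[5:10, 5:10] = 1.0
        mi = moment_invariants(img)
        assert abs(mi.central_moments[1, 1]) < 1e-9
        assert abs(mi.central_moments[3, 0]) < 1e-9
        assert abs(mi.central_moments[0, 3]) < 1e-9

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError, match="zero-mass"):
            moment_invariants(np.zeros((5, 5)))


class TestAssembleFeatures:
    def test_deterministic(self, rng):
        img = rng.integers(0, 256, (32, 32))
        cfg = FeatureConfig(frt_prime=31)
        a = assemble_features(img, cfg)
        b = assemble_features(img, cfg)
        assert np.array_equal(a.values, b.values)
        assert a.names == b.names and a.config_hash == b.config_hash

    def test_glrlm_subset_length(self, rng):
        img = rng.integers(0, 256, (16, 16))
        fv = assemble_features(img, FeatureConfig(blocks=("glrlm",)))
        assert len(fv.values) == 28

    @pytest.mark.parametrize(
        "blocks,extra",
        [(("glrlm", "mif"), 7), (("glrlm", "eltp"), 20), (("glrlm", "frt", "mif", "eltp"), None)],
    )
    def test_incremental_subsets(self, blocks, extra, rng):
        img = rng.integers(0, 256, (16, 16))
        fv = assemble_features(img, FeatureConfig(blocks=blocks, frt_prime=13))
        if extra is not None:
            assert len(fv.values) == 28 + extra
        assert len(set(fv.names)) == len(fv.names)

    def test_hash_tracks_config(self):
        assert FeatureConfig().config_hash() != FeatureConfig(gray_bins=8).config_hash()

    def test_unknown_block_rejected(self):
        with pytest.raises(ValueError):
            FeatureConfig(blocks=("glcm",))
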