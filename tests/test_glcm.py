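"""Co-occurrence matrices and Haralick features against closed forms and a
brute-force pair-counting oracle."""

import numpy as np
import pytest
from _oracles import glcm_bruteforce

import mldstnet as m
from mldstnet.errors import ContractError, ParameterError
from mldstnet.glcm import quantize


def _img(arr, levels=256):
    return m.GrayImage(np.asarray(arr), levels=levels)


class TestComputeGLCM:
    def test_constant_image_single_entry(self):
        spec = m.GLCMSpec(angles=(0,), quant_levels=16)
        mats = m.compute_glcm(_img(np.full((4, 4), 100)), spec)
        P = mats[0]
        v = (100 * 16) // 256
        assert P[v, v] == pytest.approx(1.0)
        assert P.sum() == pytest.approx(1.0)
        assert np.count_nonzero(P) == 1

    def test_checkerboard_columns_example(self):
        """[[0,1],[0,1]] at d=1, 0 deg, symmetric: P(0,1)=P(1,0)=0.5."""
        spec = m.GLCMSpec(angles=(0,), quant_levels=2)
        mats = m.compute_glcm(_img([[0, 255], [0, 255]]), spec)
        assert mats[0] == pytest.approx(np.array([[0, 0.5], [0.5, 0]]))

    def test_symmetric_and_normalized(self):
        rng = np.random.default_rng(3)
        img = _img(rng.integers(0, 256, (20, 20)))
        mats = m.compute_glcm(img, m.GLCMSpec())
        for P in mats.values():
            assert P.sum() == pytest.approx(1.0)
            assert np.allclose(P, P.T)

    def test_matches_bruteforce_pair_counter(self):
        """Oracle agreement on 20 random small images, all four angles."""
        rng = np.random.default_rng(99)
        spec = m.GLCMSpec(quant_levels=8)
        for _ in range(20):
            side = int(rng.integers(4, 17))
            img = _img(rng.integers(0, 256, (side, side)))
            mats = m.compute_glcm(img, spec)
            q = quantize(img, spec.quant_levels)
            for angle, P in mats.items():
                expected = glcm_bruteforce(q, 8, 1, angle)
                assert np.allclose(P, expected, atol=1e-12), f"angle {angle}"

    def test_image_smaller_than_offset_rejected(self):
        with pytest.raises(ContractError):
            m.compute_glcm(_img([[1, 2]]), m.GLCMSpec(angles=(90,), distance=1))

    def test_bad_spec_rejected(self):
        with pytest.raises(ParameterError):
            m.GLCMSpec(distance=0)
        with pytest.raises(ParameterError):
            m.GLCMSpec(angles=(30,))


class TestHaralickFeatures:
    def test_constant_image_closed_forms(self):
        spec = m.GLCMSpec(angles=(0,))
        feats = m.haralick_features(m.compute_glcm(_img(np.full((6, 6), 64)), spec), spec)
        assert feats["contrast"] == pytest.approx(0.0)
        assert feats["energy"] == pytest.approx(1.0)
        assert feats["entropy"] == pytest.approx(0.0)
        assert feats["homogeneity"] == pytest.approx(1.0)
        assert feats["maximum_probability"] == pytest.approx(1.0)

    def test_checkerboard_closed_forms(self):
        spec = m.GLCMSpec(angles=(0,), quant_levels=2)
        feats = m.haralick_features(m.compute_glcm(_img([[0, 255], [0, 255]]), spec), spec)
        assert feats["contrast"] == pytest.approx(1.0)
        assert feats["energy"] == pytest.approx(0.5)

    def test_entropy_bounded_by_log_levels_squared(self):
        rng = np.random.default_rng(11)
        spec = m.GLCMSpec(quant_levels=16)
        for _ in range(5):
            img = _img(rng.integers(0, 256, (15, 15)))
            feats = m.haralick_features(m.compute_glcm(img, spec), spec)
            assert feats["entropy"] <= np.log(16**2) + 1e-12

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ContractError):
            m.haralick_features({0: np.ones((4, 4))}, m.GLCMSpec())

    def test_difference_based_features_shift_invariant(self):
        """With quantization held fixed (identity), a constant intensity shift
        leaves difference/centered features unchanged."""
        rng = np.random.default_rng(4)
        base = rng.integers(0, 14, (12, 12))
        spec = m.GLCMSpec(quant_levels=16)
        f1 = m.haralick_features(m.compute_glcm(_img(base, levels=16), spec), spec)
        f2 = m.haralick_features(m.compute_glcm(_img(base + 2, levels=16), spec), spec)
        for name in (
            "contrast", "dissimilarity", "energy", "entropy", "homogeneity",
            "maximum_probability", "correlation", "cluster_shade",
            "cluster_prominence", "sum_of_squares", "sum_variance",
            "difference_variance", "difference_entropy", "sum_entropy",
            "imc1", "imc2", "inverse_difference",
        ):
            assert f1[name] == pytest.approx(f2[name], abs=1e-10), name

    def test_concat_aggregation_dimensions(self):
        img = _img(np.random.default_rng(0).integers(0, 256, (16, 16)))
        spec = m.GLCMSpec(aggregate="concat")
        feats = m.haralick_features(m.compute_glcm(img, spec), spec)
        assert len(feats) == len(m.FEATURE_NAMES) * 4


class TestFeaturesForDataset:
    def test_shape_and_determinism(self, phantoms30):
        t1 = m.features_for_dataset(phantoms30.images, phantoms30.labels)
        t2 = m.features_for_dataset(phantoms30.images, phantoms30.labels)
        assert t1.shape == (30, len(m.FEATURE_NAMES) + 1)
        assert t1.equals(t2)
        assert list(t1.columns[:-1]) == list(m.FEATURE_NAMES)
        assert t1.columns[-1] == "label"

    def test_malignant_contrast_exceeds_benign_at_matched_seeds(self):
        """Texture separates the margin phenotypes: mean GLCM contrast of
        malignant phantoms is higher, checked over 20 matched seed pairs."""
        spec = m.GLCMSpec()
        wins = 0
        for seed in range(20):
            mal, _ = m.generate_phantom(m.PhantomSpec(class_label="malignant", seed=seed))
            ben, _ = m.generate_phantom(m.PhantomSpec(class_label="benign", seed=seed))
            cm = m.haralick_features(m.compute_glcm(mal, spec), spec)["contrast"]
            cb = m.haralick_features(m.compute_glcm(ben, spec), spec)["contrast"]
            wins += cm > cb
        assert wins >= 18

    def test_length_mismatch_rejected(self, phantoms30):
        with pytest.raises(ContractError):
            m.features_for_dataset(phantoms30.images, phantoms30.labels[:-1])
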