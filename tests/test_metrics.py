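"""Quality metrics: COV, MSCN/AGGD/BRISQUE features, NIQE distance."""

import numpy as np
import pytest

from fnlm import (
    DegenerateInputError,
    DenoiseParams,
    DimensionError,
    InsufficientDataError,
    MSCNField,
    NIQEModel,
    NoiseSpec,
    PhantomSpec,
    ROISpec,
    UndefinedMetricError,
    add_gaussian_noise,
    brisque_features,
    color_luminance,
    compute_mscn,
    cov_metric,
    fit_aggd,
    fit_ggd,
    fit_niqe_model,
    fnlm_denoise_color,
    generate_phantom,
    largest_background_rect,
    mvg_distance,
    niqe_score,
    paired_products,
)


class TestCOV:
    def test_worked_example(self):
        img = np.array([[0.1, 0.2], [0.3, 0.4]])
        st = cov_metric(img, ROISpec(0, 0, 2, 2))
        assert st.mean == pytest.approx(0.25)
        assert st.std == pytest.approx(0.1118, abs=1e-4)
        assert st.cov == pytest.approx(0.4472, abs=1e-4)

    def test_constant_roi_is_zero(self):
        img = np.full((4, 4), 0.5)
        assert cov_metric(img, ROISpec(1, 1, 2, 2)).cov == 0.0

    def test_scale_invariance(self, rng):
        img = rng.uniform(0.1, 0.3, size=(8, 8))
        roi = ROISpec(1, 2, 5, 4)
        assert cov_metric(3 * img, roi).cov == pytest.approx(
            cov_metric(img, roi).cov, rel=1e-12
        )

    def test_zero_mean_undefined(self):
        with pytest.raises(UndefinedMetricError):
            cov_metric(np.zeros((4, 4)), ROISpec(0, 0, 2, 2))

    def test_roi_outside_image_rejected(self):
        with pytest.raises(DimensionError):
            cov_metric(np.ones((4, 4)), ROISpec(2, 2, 4, 4))


class TestMSCN:
    def test_constant_image_gives_zero_coefficients(self):
        field = compute_mscn(np.full((16, 16), 0.3))
        assert np.abs(field.coefficients).max() < 1e-12

    def test_offset_invariance(self, rng):
        img = rng.uniform(0.1, 0.6, size=(24, 24))
        a = compute_mscn(img).coefficients
        b = compute_mscn(img + 0.3).coefficients
        assert np.abs(a - b).max() < 1e-9

    def test_coefficients_near_zero_mean_on_noise(self):
        rng = np.random.default_rng(99)
        img = rng.normal(0.5, 0.1, size=(256, 256)).clip(0, 1)
        field = compute_mscn(img)
        assert abs(field.coefficients.mean()) < 0.01

    def test_deviation_field_nonnegative_and_consistent(self, rng):
        img = rng.uniform(0, 1, size=(16, 16))
        f = compute_mscn(img)
        assert np.all(f.local_var_field >= 0)
        recon = (img * 255 - f.local_mean) / (f.local_var_field + f.C)
        assert np.abs(recon - f.coefficients).max() < 1e-12


class TestPairedProducts:
    def _field(self, coeffs):
        z = np.zeros_like(coeffs)
        return MSCNField(coefficients=coeffs, local_mean=z, local_var_field=z, C=1.0)

    def test_zero_field_propagates(self):
        h, v, d1, d2 = paired_products(self._field(np.zeros((4, 4))))
        for p in (h, v, d1, d2):
            assert np.all(p == 0.0)

    def test_checkerboard_signs(self):
        yy, xx = np.mgrid[0:6, 0:6]
        board = np.where((yy + xx) % 2 == 0, 1.0, -1.0)
        h, v, d1, d2 = paired_products(self._field(board))
        assert np.all(h == -1.0) and np.all(v == -1.0)
        assert np.all(d1 == 1.0) and np.all(d2 == 1.0)

    def test_horizontal_equals_vertical_of_transpose(self, rng):
        c = rng.normal(size=(5, 7))
        h, _, _, _ = paired_products(self._field(c))
        _, vt, _, _ = paired_products(self._field(c.T))
        assert np.array_equal(h, vt.T)


class TestGeneralizedGaussianFits:
    def test_aggd_recovers_gaussian_shape(self):
        x = np.random.default_rng(42).normal(0, 1, 100_000)
        p = fit_aggd(x)
        assert 1.9 <= p.shape_alpha <= 2.1
        assert p.scale_left == pytest.approx(p.scale_right, rel=0.05)
        assert abs(p.mean_eta) < 0.05

    def test_aggd_recovers_laplacian_shape(self):
        x = np.random.default_rng(42).laplace(0, 1, 100_000)
        p = fit_aggd(x)
        assert 0.9 <= p.shape_alpha <= 1.1

    def test_aggd_detects_asymmetry(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([-np.abs(rng.normal(0, 0.5, 50_000)),
                            np.abs(rng.normal(0, 2.0, 50_000))])
        p = fit_aggd(x)
        assert p.scale_right > p.scale_left
        assert p.mean_eta > 0

    def test_degenerate_samples_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_aggd(np.full(100, 0.7))
        with pytest.raises(DegenerateInputError):
            fit_aggd(np.abs(np.random.default_rng(0).normal(size=100)))

    def test_ggd_recovers_gaussian(self):
        x = np.random.default_rng(42).normal(0, 1, 100_000)
        alpha, var = fit_ggd(x)
        assert 1.9 <= alpha <= 2.1
        assert var == pytest.approx(1.0, rel=0.05)


class TestBRISQUEFeatures:
    def test_feature_length_is_36(self, rng):
        img = rng.uniform(0, 1, size=(64, 64))
        f = brisque_features(img)
        assert f.values.shape == (36,)
        assert np.all(np.isfinite(f.values))

    def test_offset_shift_leaves_features_unchanged(self, rng):
        img = rng.uniform(0.1, 0.5, size=(64, 64))
        a = brisque_features(img).values
        b = brisque_features(img + 0.2).values
        assert np.abs(a - b).max() < 1e-6

    def test_noise_moves_features(self, small_phantom):
        lum = color_luminance(small_phantom[0])
        noisy = np.clip(
            lum + np.random.default_rng(1).normal(0, 0.1, lum.shape), 0, 1
        )
        a = brisque_features(lum).values
        b = brisque_features(noisy).values
        assert np.linalg.norm(a - b) > 0
        # noise whitens the MSCN distribution: first-scale GGD shape moves up
        assert b[0] > a[0]

    def test_too_small_image_rejected(self):
        with pytest.raises(DimensionError):
            brisque_features(np.zeros((16, 16)))


class TestMVGDistance:
    def test_identical_means_give_zero(self, rng):
        v = rng.normal(size=4)
        S = np.eye(4)
        assert mvg_distance(v, v, S, 2 * S) == 0.0

    def test_unit_displacement_identity_covariance(self):
        d = mvg_distance(np.array([1.0, 0.0]), np.zeros(2), np.eye(2), np.eye(2))
        assert d == pytest.approx(1.0, abs=1e-8)

    def test_symmetric_under_swap(self, rng):
        v1, v2 = rng.normal(size=3), rng.normal(size=3)
        A = rng.normal(size=(3, 3))
        B = rng.normal(size=(3, 3))
        S1, S2 = A @ A.T + np.eye(3), B @ B.T + np.eye(3)
        assert mvg_distance(v1, v2, S1, S2) == mvg_distance(v2, v1, S2, S1)

    def test_sqrt_variant(self):
        d = mvg_distance(
            np.array([2.0, 0.0]), np.zeros(2), np.eye(2), np.eye(2), sqrt=True
        )
        assert d == pytest.approx(2.0, abs=1e-8)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            mvg_distance(np.zeros(2), np.zeros(3), np.eye(2), np.eye(3))


@pytest.fixture(scope="module")
def niqe_setup():
    corpus = []
    for s in range(20):
        img, _ = generate_phantom(
            PhantomSpec(height=128, width=128, n_brown=5, n_blue=6,
                        radius_range=(5.0, 10.0), seed=100 + s)
        )
        corpus.append(color_luminance(img))
    model = fit_niqe_model(corpus, patch_size=32, sharpness_fraction=0.75)
    test_img, _ = generate_phantom(
        PhantomSpec(height=128, width=128, n_brown=5, n_blue=6,
                    radius_range=(5.0, 10.0), seed=7)
    )
    return model, test_img


class TestNIQE:
    def test_model_dimensions(self, niqe_setup):
        model, _ = niqe_setup
        assert model.mean_vec.shape == (36,)
        assert model.covariance.shape == (36, 36)
        assert np.allclose(model.covariance, model.covariance.T)

    def test_constant_corpus_rejected(self):
        corpus = [np.full((64, 64), 0.5) for _ in range(5)]
        with pytest.raises((DegenerateInputError, InsufficientDataError)):
            fit_niqe_model(corpus, patch_size=32)

    def test_pristine_scores_below_noisy(self, niqe_setup):
        model, img = niqe_setup
        lum = color_luminance(img)
        noisy = np.clip(
            lum + np.random.default_rng(3).normal(0, 0.1, lum.shape), 0, 1
        )
        assert niqe_score(lum, model) < niqe_score(noisy, model)

    def test_score_offset_invariant(self, niqe_setup):
        # Checked on a textured (noisy) image: on near-degenerate smooth
        # patches the moment-matched AGGD shape sits on the flat part of the
        # moment-ratio curve, where the grid argmin is not float-stable.
        model, img = niqe_setup
        lum = color_luminance(img) * 0.5  # headroom for the offset
        noisy = np.clip(
            lum + np.random.default_rng(3).normal(0, 0.025, lum.shape), 0, 0.75
        )
        a = niqe_score(noisy, model)
        b = niqe_score(noisy + 0.2, model)
        assert b == pytest.approx(a, rel=1e-4)

    def test_model_roundtrips_through_file(self, niqe_setup, tmp_path):
        model, img = niqe_setup
        path = tmp_path / "model.json"
        model.save(path)
        loaded = NIQEModel.load(path)
        assert np.allclose(loaded.mean_vec, model.mean_vec)
        assert np.allclose(loaded.covariance, model.covariance)
        lum = color_luminance(img)
        assert niqe_score(lum, loaded) == pytest.approx(
            niqe_score(lum, model), rel=1e-9
        )


class TestEndToEnd:
    def test_denoising_reduces_background_cov(self, noisy_phantom):
        noisy, clean, labels = noisy_phantom
        roi = largest_background_rect(labels)
        p = DenoiseParams(d=0.05, kernel_size=3, search_size=7)
        den = fnlm_denoise_color(noisy, p)
        cov_before = cov_metric(color_luminance(noisy), roi).cov
        cov_after = cov_metric(color_luminance(den), roi).cov
        assert cov_after < cov_before
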