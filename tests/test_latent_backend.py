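"""Latent class model, quality metrics, reconstruction metrics, toy autoencoder."""

import numpy as np
import pytest

from deltamarch.latent_backend import (
    NotFittedError,
    destandardize,
    fit_latent_class_model,
    latent_quality_metrics,
    reconstruction_metrics,
    standardize,
    train_toy_autoencoder,
)
from deltamarch.synthetic_tissue import SceneParams, analytic_backend, make_cohort


def _analytic_codes(n_per_grade, seed=0):
    """Codes drawn as the analytic cohort generator draws them (no rendering)."""
    rng = np.random.default_rng(seed)
    codes, grades = [], []
    for g in (1, 2, 3, 4):
        for _ in range(n_per_grade):
            codes.append(
                np.array([
                    float(g),
                    rng.integers(6, 11),
                    rng.integers(4, 8),
                    np.clip(rng.normal(0, 0.15), np.log(0.8), np.log(1.25)),
                ])
            )
            grades.append(g)
    return np.array(codes), np.array(grades)


class TestStandardize:
    def test_mean_code_maps_to_zero(self):
        codes, grades = _analytic_codes(30)
        model = fit_latent_class_model(codes, grades)
        assert np.allclose(standardize(model.mu, model), 0.0)

    def test_round_trip(self):
        codes, grades = _analytic_codes(30)
        model = fit_latent_class_model(codes, grades)
        x = codes[5]
        assert np.max(np.abs(destandardize(standardize(x, model), model) - x)) < 1e-10

    def test_identity_when_unit_stats(self):
        codes, grades = _analytic_codes(30)
        model = fit_latent_class_model(codes, grades)
        model.mu = np.zeros(model.d)
        model.sigma = np.ones(model.d)
        x = np.array([1.0, -2.0, 3.0, 0.5])
        assert np.array_equal(standardize(x, model), x)

    def test_unfitted_model_rejected(self):
        codes, grades = _analytic_codes(30)
        model = fit_latent_class_model(codes, grades)
        model.fitted = False
        with pytest.raises(NotFittedError):
            standardize(np.zeros(4), model)


class TestFitLatentClassModel:
    def test_separable_clouds_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, (50, 3))
        b = rng.normal(5, 0.1, (50, 3))
        model = fit_latent_class_model(np.vstack([a, b]), [1] * 50 + [2] * 50)
        assert model.training_accuracy == 1.0
        assert model.weights.shape == (2, 3)

    def test_recovers_grade_axis(self):
        codes, grades = _analytic_codes(125)  # 500 samples
        model = fit_latent_class_model(codes, grades)
        w4 = model.weight_vector(4)
        cos = w4[0] / np.linalg.norm(w4)  # grade axis is e0 in standardized space
        assert cos > 0.9

    def test_sample_order_invariance(self):
        codes, grades = _analytic_codes(40, seed=3)
        m1 = fit_latent_class_model(codes, grades)
        perm = np.random.default_rng(1).permutation(len(codes))
        m2 = fit_latent_class_model(codes[perm], grades[perm])
        assert np.max(np.abs(m1.weights - m2.weights)) < 1e-6

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            fit_latent_class_model(np.random.default_rng(0).normal(size=(20, 3)), [1] * 20)

    def test_constant_dimension_rejected(self):
        codes = np.random.default_rng(0).normal(size=(40, 3))
        codes[:, 1] = 2.0
        with pytest.raises(ValueError, match="sigma"):
            fit_latent_class_model(codes, [1, 2] * 20)


class TestLatentQualityMetrics:
    def test_within_slide_clusters(self):
        rng = np.random.default_rng(0)
        codes, slides, grades = [], [], []
        for s in range(5):
            center = rng.normal(0, 100, 4)
            for _ in range(12):
                codes.append(center + rng.normal(0, 0.01, 4))
                slides.append(f"s{s}")
                grades.append(1 + s % 4)
        m = latent_quality_metrics(codes, slides, grades, k=5)
        assert m["same_slide_fraction"] == 1.0

    def test_random_codes_chance_level(self):
        rng = np.random.default_rng(1)
        n = 2000
        codes = rng.normal(size=(n, 4))
        grades = np.repeat([1, 2, 3, 4], n // 4)
        m = latent_quality_metrics(codes, ["s"] * n, grades, k=10)
        assert abs(m["same_grade_fraction"] - 0.25) < 0.03

    def test_separated_grades_perfect_lda(self):
        rng = np.random.default_rng(2)
        codes = np.vstack([rng.normal(10 * g, 0.1, (30, 3)) for g in (1, 2, 3, 4)])
        grades = np.repeat([1, 2, 3, 4], 30)
        m = latent_quality_metrics(codes, ["s"] * 120, grades, k=5)
        assert m["low_vs_high_linear_accuracy"] == 1.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="k\\+1"):
            latent_quality_metrics(np.zeros((5, 2)), ["a"] * 5, [1] * 5, k=10)

    def test_analytic_codes_beat_pixel_embedding(self, small_cohort, backend):
        """Semantic codes group same-grade patches better than raw pixels do."""
        patches, _ = small_cohort
        grades = [p.grade_label for p in patches]
        slides = [p.slide_id for p in patches]
        codes = [backend.encode_patch(p) for p in patches]
        pixel = [p.image[::8, ::8].ravel() for p in patches]  # downsampled pixel embedding
        m_code = latent_quality_metrics(codes, slides, grades, k=10)
        m_pix = latent_quality_metrics(pixel, slides, grades, k=10)
        assert m_code["same_grade_fraction"] > m_pix["same_grade_fraction"]


class TestReconstructionMetrics:
    def test_identical_images(self):
        img = np.random.default_rng(0).random((32, 32, 3))
        m = reconstruction_metrics(img, img)
        assert m["mse"] == 0.0 and m["ssim"] == 1.0 and np.isinf(m["psnr"])

    def test_constant_offset_closed_form(self):
        a = np.full((64, 64), 0.5)
        b = np.full((64, 64), 0.6)
        m = reconstruction_metrics(a, b)
        assert abs(m["mse"] - 0.01) < 1e-12
        assert abs(m["psnr"] - 20.0) < 1e-9

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.random((16, 16, 3)), rng.random((16, 16, 3))
        m1, m2 = reconstruction_metrics(a, b), reconstruction_metrics(b, a)
        assert m1["mse"] == m2["mse"]
        assert abs(m1["ssim"] - m2["ssim"]) < 1e-12

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            reconstruction_metrics(np.zeros((8, 8)), np.zeros((9, 9)))


@pytest.fixture(scope="module")
def trained():
    patches, _ = make_cohort(40, seed=7)  # 160 patches
    return patches, train_toy_autoencoder(patches, patch_size=32, seed=0)


class TestToyAutoencoder:
    def test_reconstruction_quality_held_out(self, trained):
        """Held-out SSIM above the pilot-calibrated desk-scale threshold."""
        _, bk = trained
        held, _ = make_cohort(5, seed=900)
        ssims = []
        for p in held:
            small = bk._fit_size(p.image)
            recon = bk.decode(bk.encode_image(p.image))
            ssims.append(reconstruction_metrics(small, recon)["ssim"])
        assert np.mean(ssims) > 0.4

    def test_loss_decreases(self, trained):
        _, bk = trained
        hist = bk.loss_history
        assert hist[-1] < hist[0]

    def test_untrained_network_features_computable(self):
        from deltamarch.delta_march import compute_delta_map
        from deltamarch.latent_backend import _build_toy_nets

        enc, _ = _build_toy_nets(32, 16, np.random.default_rng(0))
        rng = np.random.default_rng(1)
        a, b = rng.random((32, 32, 3)), rng.random((32, 32, 3))
        dm = compute_delta_map(a, b, enc, depth=6)
        assert dm.raw.shape == (32, 32) and (dm.raw >= 0).all()

    def test_seeded_training_reproducible(self):
        patches, _ = make_cohort(6, seed=8)
        b1 = train_toy_autoencoder(patches, patch_size=32, epochs=2, seed=4)
        b2 = train_toy_autoencoder(patches, patch_size=32, epochs=2, seed=4)
        assert b1.loss_history == b2.loss_history


def test_toy_backend_save_load_round_trip(trained, tmp_path):
    from deltamarch.latent_backend import ToyAutoencoderBackend

    patches, bk = trained
    bk.save(tmp_path / "bundle")
    loaded = ToyAutoencoderBackend.load(tmp_path / "bundle")
    img = patches[0].image
    assert np.allclose(loaded.encode_image(img), bk.encode_image(img))
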