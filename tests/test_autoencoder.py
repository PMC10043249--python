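import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from planqa.autoencoder import (
    AEConfig,
    ConfigError,
    build_autoencoder,
    check_fingerprint,
    fit_autoencoder,
    load_model,
    recon_loss,
    reconstruct,
    sample_errors,
    save_model,
    train,
)
from planqa.schema import encode_table
from planqa.synthetic import GenConfig, generate_dataset

from conftest import random_mixed_matrix


class TestBuild:
    def test_depth1_structure(self):
        model = build_autoencoder(AEConfig(depth=1, latent_dim=4), input_dim=10)
        assert model.widths == [10, 4, 10]
        (w_e, b_e), = model.encoder_parameters()
        (w_d, b_d), = model.decoder_parameters()
        assert w_e.shape == (10, 4) and w_d.shape == (4, 10)

    def test_depth6_palindromic(self):
        model = build_autoencoder(AEConfig(depth=6), input_dim=58)
        assert len(model.encoder_parameters()) == 6
        assert len(model.decoder_parameters()) == 6
        assert model.widths == model.widths[::-1]

    @pytest.mark.parametrize("depth", range(1, 10))
    def test_symmetry_all_depths(self, depth):
        model = build_autoencoder(AEConfig(depth=depth), input_dim=58)
        enc_w = [w.shape[1] for w, _ in model.encoder_parameters()]
        dec_w = [w.shape[1] for w, _ in model.decoder_parameters()]
        assert dec_w[::-1][1:] == enc_w[:-1]
        assert dec_w[-1] == 58
        assert enc_w[-1] == 8
        assert all(a >= b for a, b in zip(enc_w, enc_w[1:]))  # monotone taper

    def test_seed_determinism(self):
        a = build_autoencoder(AEConfig(depth=3, seed=11), input_dim=20)
        b = build_autoencoder(AEConfig(depth=3, seed=11), input_dim=20)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_latent_too_large(self):
        with pytest.raises(ConfigError):
            build_autoencoder(AEConfig(depth=1, latent_dim=10), input_dim=10)

    def test_explicit_widths(self):
        cfg = AEConfig(depth=2, hidden_widths=[12, 8], latent_dim=8)
        model = build_autoencoder(cfg, input_dim=20)
        assert model.widths == [20, 12, 8, 12, 20]

    def test_bad_config(self):
        with pytest.raises(ConfigError):
            AEConfig(depth=0)
        with pytest.raises(ConfigError):
            AEConfig(dropout_rate=1.0)
        with pytest.raises(ConfigError):
            AEConfig(depth=2, hidden_widths=[4])


class TestReconstruct:
    def test_zero_model_outputs(self, small_encoded):
        model = build_autoencoder(
            AEConfig(depth=2), small_encoded.n_dims, small_encoded.mask
        )
        for i in range(model.n_layers):
            model.weights[i][:] = 0.0
            model.biases[i][:] = 0.0
        out = reconstruct(model, small_encoded.values)
        b = small_encoded.mask.binary_idx
        c = small_encoded.mask.continuous_idx
        assert np.all(out[:, b] == 0.5)
        assert np.all(out[:, c] == 0.0)

    def test_single_row_shape(self, small_encoded):
        model = build_autoencoder(
            AEConfig(depth=2), small_encoded.n_dims, small_encoded.mask
        )
        out = reconstruct(model, small_encoded.values[0])
        assert out.shape == (1, small_encoded.n_dims)

    def test_inference_deterministic(self, small_encoded):
        model = build_autoencoder(
            AEConfig(depth=3, dropout_rate=0.5), small_encoded.n_dims, small_encoded.mask
        )
        a = reconstruct(model, small_encoded.values)
        b = reconstruct(model, small_encoded.values)
        np.testing.assert_array_equal(a, b)

    def test_width_mismatch(self, small_encoded):
        model = build_autoencoder(AEConfig(depth=1), 10)
        with pytest.raises(ValueError):
            reconstruct(model, small_encoded.values)

    def test_binary_outputs_in_open_interval(self, small_encoded):
        model = build_autoencoder(
            AEConfig(depth=2, seed=3), small_encoded.n_dims, small_encoded.mask
        )
        out = reconstruct(model, small_encoded.values)
        b = small_encoded.mask.binary_idx
        assert np.all((out[:, b] > 0) & (out[:, b] < 1))


class TestReconLoss:
    def test_perfect_reconstruction(self, small_encoded):
        X = small_encoded.values
        X_hat = X.astype(float).copy()
        b = small_encoded.mask.binary_idx
        X_hat[:, b] = np.clip(X_hat[:, b], 1e-9, 1 - 1e-9)
        total, bce, mse = recon_loss(X_hat, X, small_encoded.mask, 0.99)
        assert total < 1e-6 and mse == 0.0

    def test_half_predictions_give_ln2(self):
        rng = np.random.default_rng(0)
        X_hat, X, mask = random_mixed_matrix(rng, n_cont=0)
        X_hat[:, :] = 0.5
        _, bce, _ = recon_loss(X_hat, X, mask, 0.5)
        assert bce == pytest.approx(np.log(2), abs=1e-12)

    def test_lambda_scales_mse(self):
        rng = np.random.default_rng(1)
        X_hat, X, mask = random_mixed_matrix(rng, n_binary=0)
        total, bce, mse = recon_loss(X_hat, X, mask, 0.99)
        assert bce == 0.0
        assert total == pytest.approx(0.99 * mse, abs=1e-12)

    def test_extreme_predictions_clipped(self):
        rng = np.random.default_rng(2)
        X_hat, X, mask = random_mixed_matrix(rng, n_cont=0)
        X_hat[:, :] = 1.0  # would be infinite BCE without clipping
        total, bce, _ = recon_loss(X_hat, X, mask, 1.0)
        assert np.isfinite(total)
        assert bce <= -np.log(1e-7) + 1e-9

    def test_shape_mismatch(self):
        rng = np.random.default_rng(3)
        X_hat, X, mask = random_mixed_matrix(rng)
        with pytest.raises(ValueError):
            recon_loss(X_hat[:, :-1], X, mask, 1.0)


@settings(max_examples=50, deadline=None)
@given(
    st.integers(min_value=0, max_value=10_000),
    st.floats(min_value=0.0, max_value=2.0),
)
def test_loss_decomposition_property(seed, lam):
    rng = np.random.default_rng(seed)
    X_hat, X, mask = random_mixed_matrix(rng)
    total, bce, mse = recon_loss(X_hat, X, mask, lam)
    assert total == pytest.approx(bce + lam * mse, abs=1e-10)
    assert bce >= 0 and mse >= 0


class TestTrain:
    def test_memorizes_identical_rows(self, small_encoded):
        X = np.tile(small_encoded.values[:1], (16, 1))
        from planqa.schema import EncodedMatrix

        data = EncodedMatrix(values=X, mask=small_encoded.mask)
        cfg = AEConfig(depth=1, latent_dim=4, epochs=300, batch_size=8, seed=0)
        model = build_autoencoder(cfg, data.n_dims, data.mask)
        init = recon_loss(
            reconstruct(model, X), X, data.mask, cfg.lambda_weight
        )[0]
        result = train(model, data, cfg)
        assert result.history["total"][-1] < 0.01 * init

    def test_deterministic_histories(self, small_encoded, fast_config):
        r1 = fit_autoencoder(small_encoded, fast_config)
        r2 = fit_autoencoder(small_encoded, fast_config)
        np.testing.assert_array_equal(r1.history["total"], r2.history["total"])
        s1 = sample_errors(r1.model, small_encoded, fast_config.lambda_weight)
        s2 = sample_errors(r2.model, small_encoded, fast_config.lambda_weight)
        np.testing.assert_array_equal(s1, s2)

    def test_lambda_zero_total_equals_bce(self, small_encoded):
        cfg = AEConfig(depth=2, latent_dim=4, epochs=30, lambda_weight=0.0, seed=1)
        result = fit_autoencoder(small_encoded, cfg)
        np.testing.assert_array_equal(
            result.history["total"], result.history["bce"]
        )

    def test_history_length_and_finite(self, small_encoded, fast_config):
        result = fit_autoencoder(small_encoded, fast_config)
        assert len(result.history["total"]) == fast_config.epochs
        for key in ("total", "bce", "mse"):
            assert np.all(np.isfinite(result.history[key]))
            assert np.all(result.history[key] >= 0)

    def test_too_few_rows(self, small_encoded):
        from planqa.schema import EncodedMatrix

        data = EncodedMatrix(
            values=small_encoded.values[:1], mask=small_encoded.mask
        )
        cfg = AEConfig(depth=1, latent_dim=4)
        model = build_autoencoder(cfg, data.n_dims, data.mask)
        with pytest.raises(ValueError):
            train(model, data, cfg)


class TestSampleErrors:
    def test_permutation_equivariance(self, small_encoded, fast_config):
        result = fit_autoencoder(small_encoded, fast_config)
        scores = sample_errors(result.model, small_encoded, 0.99)
        perm = np.random.default_rng(0).permutation(small_encoded.n_plans)
        from planqa.schema import EncodedMatrix

        permuted = EncodedMatrix(
            values=small_encoded.values[perm], mask=small_encoded.mask
        )
        scores_p = sample_errors(result.model, permuted, 0.99)
        np.testing.assert_allclose(scores_p, scores[perm], rtol=1e-12)

    def test_mean_equals_batch_loss(self, small_encoded, fast_config):
        result = fit_autoencoder(small_encoded, fast_config)
        scores = sample_errors(result.model, small_encoded, 0.99)
        X_hat = reconstruct(result.model, small_encoded.values)
        total, _, _ = recon_loss(
            X_hat, small_encoded.values, small_encoded.mask, 0.99
        )
        assert scores.mean() == pytest.approx(total, rel=1e-12)

    def test_one_score_per_row(self, small_encoded, fast_config):
        result = fit_autoencoder(small_encoded, fast_config)
        scores = sample_errors(result.model, small_encoded, 0.99)
        assert scores.shape == (small_encoded.n_plans,)


class TestCheckpoint:
    def test_roundtrip(self, tmp_path, small_encoded, fast_config):
        result = fit_autoencoder(small_encoded, fast_config)
        path = tmp_path / "model.json"
        save_model(result.model, fast_config, path)
        model, cfg = load_model(path)
        assert cfg == fast_config
        np.testing.assert_allclose(
            reconstruct(model, small_encoded.values),
            reconstruct(result.model, small_encoded.values),
            rtol=1e-12,
        )

    def test_fingerprint_mismatch_rejected(self, small_encoded, fast_config):
        from planqa.schema import EncodedMatrix

        result = fit_autoencoder(small_encoded, fast_config)
        check_fingerprint(result.model, small_encoded)  # same layout: fine
        rng = np.random.default_rng(0)
        _, X, other_mask = random_mixed_matrix(rng, n_binary=30, n_cont=28)
        other = EncodedMatrix(values=X, mask=other_mask)
        with pytest.raises(ValueError, match="fingerprint"):
            check_fingerprint(result.model, other)
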