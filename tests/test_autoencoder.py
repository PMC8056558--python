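import dataclasses

import numpy as np
import pytest
from scipy.stats import binom

from dtidae import (
    AutoencoderParams,
    CorruptionRecord,
    TrainingConfig,
    TrainingDivergedError,
    corrupt,
    decode,
    encode,
    initialize_params,
    load_params,
    loss_gradient,
    masked_denoising_loss,
    reconstruct,
    save_params,
    train,
    train_samples,
)
from dtidae.preprocessing import FingerprintTargetMatrix
from dtidae.synthetic import paper_scale_fixture
from dtidae.preprocessing import preprocess


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def forward_oracle(x, params):
    """Independent two-line-per-layer forward pass."""
    a = np.asarray(x, dtype=float)
    for w, b in params.all_layers():
        a = sigmoid(a @ w + b)
    return a


def zero_params(f, hidden):
    p = initialize_params(f, hidden, np.random.default_rng(0))
    return AutoencoderParams(
        [np.zeros_like(w) for w in p.encoder_weights],
        [np.zeros_like(b) for b in p.encoder_biases],
        [np.zeros_like(w) for w in p.decoder_weights],
        [np.zeros_like(b) for b in p.decoder_biases],
    )


def random_instance(rng, f=None, hidden=(4, 2)):
    f = f or int(rng.integers(3, 11))
    params = initialize_params(f, hidden, rng)
    x = rng.integers(0, 2, size=f).astype(float)
    observed = rng.random(f) < 0.7
    x = x * observed  # unobserved positions are zero by contract
    record = corrupt(x, observed, 0.3, rng)
    config = TrainingConfig(
        alpha=0.4, beta=0.6, lambda_reg=float(rng.choice([0.0 + 1e-12, 0.5, 2.0])),
        hidden_sizes=hidden, seed=0,
    )
    return x, observed, record, config, params


class TestEncodeDecode:
    def test_zero_params_give_half(self):
        params = zero_params(6, (3, 2))
        np.testing.assert_allclose(encode(np.ones(6), params), np.full(2, 0.5))
        np.testing.assert_allclose(decode(np.zeros(2), params), np.full(6, 0.5))

    def test_sigmoid_saturation(self):
        params = zero_params(1, (1,))
        params.encoder_biases[0][:] = -50.0
        assert encode(np.array([3.0]), params)[0] == pytest.approx(0.0, abs=1e-12)

    def test_encode_output_range_and_size(self, rng):
        params = initialize_params(8, (15, 5), rng)
        h = encode(rng.random(8), params)
        assert h.shape == (5,)
        assert ((h > 0) & (h < 1)).all()

    def test_matches_forward_oracle(self, rng):
        for _ in range(10):
            params = initialize_params(7, (4, 2), rng)
            x = rng.standard_normal(7)
            enc_oracle = x
            for w, b in zip(params.encoder_weights, params.encoder_biases):
                enc_oracle = sigmoid(enc_oracle @ w + b)
            np.testing.assert_allclose(encode(x, params), enc_oracle, atol=1e-12)
            np.testing.assert_allclose(
                decode(encode(x, params), params), forward_oracle(x, params), atol=1e-12
            )

    def test_dimension_mismatch(self, rng):
        params = initialize_params(7, (4, 2), rng)
        with pytest.raises(ValueError):
            encode(np.zeros(6), params)
        with pytest.raises(ValueError):
            decode(np.zeros(3), params)

    def test_params_validate_chain(self, rng):
        params = initialize_params(7, (4, 2), rng)
        params.validate()
        params.decoder_weights[-1] = params.decoder_weights[-1][:, :-1]
        with pytest.raises(ValueError):
            params.validate()


class TestCorrupt:
    def test_rate_zero_is_identity(self, rng):
        x = np.array([1.0, 0.0, 1.0])
        record = corrupt(x, np.array([True, True, True]), 0.0, rng)
        assert record.corrupted_index_set == frozenset()
        np.testing.assert_array_equal(record.corrupted_input, x)

    def test_corrupted_count_within_binomial_bounds(self):
        rng = np.random.default_rng(99)
        x = np.ones(1000)
        record = corrupt(x, np.ones(1000, dtype=bool), 0.5, rng)
        lo, hi = binom.ppf([0.005, 0.995], 1000, 0.5)
        assert lo <= len(record.corrupted_index_set) <= hi

    def test_all_unobserved(self, rng):
        x = np.zeros(5)
        record = corrupt(x, np.zeros(5, dtype=bool), 0.5, rng)
        assert record.corrupted_index_set == frozenset()
        np.testing.assert_array_equal(record.corrupted_input, np.zeros(5))

    def test_corrupted_positions_are_observed_and_zeroed(self, rng):
        x = np.ones(50)
        observed = rng.random(50) < 0.5
        record = corrupt(x * observed, observed, 0.5, rng)
        for j in record.corrupted_index_set:
            assert observed[j]
            assert record.corrupted_input[j] == 0.0

    def test_invalid_rate(self, rng):
        with pytest.raises(ValueError):
            corrupt(np.ones(3), np.ones(3, dtype=bool), 1.0, rng)


def loss_loop_oracle(x, record, reconstruction, observed, config, params):
    """Brute-force per-position loop for the masked, reweighted loss."""
    c = record.corrupted_index_set
    total = 0.0
    for j in range(len(x)):
        if not observed[j]:
            continue
        err = (x[j] - reconstruction[j]) ** 2
        total += config.alpha * err if j in c else config.beta * err
    reg = 0.0
    for w, _ in params.all_layers():
        reg += (w**2).sum()
    return total + 0.5 * config.lambda_reg * reg


class TestMaskedLoss:
    def test_perfect_reconstruction_zero_loss(self):
        config = TrainingConfig(lambda_reg=1e-12, hidden_sizes=(2,))
        params = zero_params(3, (2,))
        x = np.array([1.0, 0.0, 1.0])
        record = CorruptionRecord(corrupted_input=x, corrupted_index_set=frozenset())
        loss = masked_denoising_loss(x, record, x.copy(), np.ones(3, bool), config, params)
        assert loss == pytest.approx(0.0, abs=1e-10)

    def test_single_term_arithmetic(self):
        config = TrainingConfig(alpha=0.4, beta=0.6, lambda_reg=1e-12, hidden_sizes=(2,))
        params = zero_params(3, (2,))
        x = np.array([1.0, 0.0, 1.0])
        record = CorruptionRecord(
            corrupted_input=np.array([0.0, 0.0, 1.0]), corrupted_index_set=frozenset({0})
        )
        recon = np.array([0.0, 0.0, 1.0])
        loss = masked_denoising_loss(x, record, recon, np.ones(3, bool), config, params)
        assert loss == pytest.approx(0.4, abs=1e-9)

    def test_matches_loop_oracle(self, rng):
        for _ in range(25):
            x, observed, record, config, params = random_instance(rng)
            recon = forward_oracle(record.corrupted_input, params)
            loss = masked_denoising_loss(x, record, recon, observed, config, params)
            oracle = loss_loop_oracle(x, record, recon, observed, config, params)
            assert loss == pytest.approx(oracle, abs=1e-12)

    def test_alpha_equals_beta_reduces_to_masked_mse(self, rng):
        for _ in range(10):
            x, observed, record, config, params = random_instance(rng)
            config = dataclasses.replace(config, alpha=0.5, beta=0.5)
            recon = forward_oracle(record.corrupted_input, params)
            loss = masked_denoising_loss(x, record, recon, observed, config, params)
            mse = 0.5 * ((x - recon) ** 2)[observed].sum()
            reg = 0.5 * config.lambda_reg * sum(
                (w**2).sum() for w, _ in params.all_layers()
            )
            assert loss == pytest.approx(mse + reg, abs=1e-12)

    def test_dimension_mismatch(self, rng):
        x, observed, record, config, params = random_instance(rng, f=5)
        with pytest.raises(ValueError):
            masked_denoising_loss(x, record, np.zeros(4), observed, config, params)


def numeric_gradient(x, record, observed, config, params, h=1e-5):
    """Central finite differences through the full loss (forward recomputed)."""

    def loss_at(p):
        recon = forward_oracle(record.corrupted_input, p)
        return masked_denoising_loss(x, record, recon, observed, config, p)

    grads = params.copy()
    for plist, glist in (
        (params.encoder_weights, grads.encoder_weights),
        (params.encoder_biases, grads.encoder_biases),
        (params.decoder_weights, grads.decoder_weights),
        (params.decoder_biases, grads.decoder_biases),
    ):
        for arr, garr in zip(plist, glist):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = arr[idx]
                arr[idx] = orig + h
                up = loss_at(params)
                arr[idx] = orig - h
                down = loss_at(params)
                arr[idx] = orig
                garr[idx] = (up - down) / (2 * h)
    return grads


def flatten(params):
    return np.concatenate(
        [a.ravel() for a in params.encoder_weights + params.encoder_biases
         + params.decoder_weights + params.decoder_biases]
    )


class TestLossGradient:
    def test_all_unobserved_zero_gradient(self, rng):
        f = 5
        params = initialize_params(f, (4, 2), rng)
        config = TrainingConfig(lambda_reg=1e-12, hidden_sizes=(4, 2))
        x = np.zeros(f)
        record = corrupt(x, np.zeros(f, bool), 0.3, rng)
        grads = loss_gradient(x, record, np.zeros(f, bool), config, params)
        assert np.allclose(flatten(grads), 0.0, atol=1e-12)

    def test_matches_finite_differences(self, rng):
        worst = 0.0
        for _ in range(20):
            x, observed, record, config, params = random_instance(rng)
            analytic = loss_gradient(x, record, observed, config, params)
            numeric = numeric_gradient(x, record, observed, config, params)
            fa, fn = flatten(analytic), flatten(numeric)
            scale = max(np.abs(fn).max(), 1e-8)
            worst = max(worst, np.abs(fa - fn).max() / scale)
        assert worst < 1e-5

    def test_regularizer_only_gradient(self, rng):
        # zero data error: nothing observed, so only lambda*W remains
        f = 6
        params = initialize_params(f, (3,), rng)
        config = TrainingConfig(lambda_reg=2.5, hidden_sizes=(3,))
        x = np.zeros(f)
        record = corrupt(x, np.zeros(f, bool), 0.0, rng)
        grads = loss_gradient(x, record, np.zeros(f, bool), config, params)
        for (gw, gb), (w, b) in zip(grads.all_layers(), params.all_layers()):
            np.testing.assert_allclose(gw, config.lambda_reg * w, atol=1e-12)
            np.testing.assert_allclose(gb, np.zeros_like(b), atol=1e-12)

    def test_perturbing_unobserved_target_keeps_gradient(self, rng):
        x, observed, record, config, params = random_instance(rng, f=8)
        if observed.all():
            observed[0] = False
        grads = loss_gradient(x, record, observed, config, params)
        x2 = x.copy()
        x2[~observed] += rng.standard_normal((~observed).sum())
        grads2 = loss_gradient(x2, record, observed, config, params)
        np.testing.assert_array_equal(flatten(grads), flatten(grads2))


class TestMaskingContract:
    def test_perturbing_unobserved_input_keeps_loss(self, rng):
        for _ in range(10):
            x, observed, record, config, params = random_instance(rng, f=9)
            config = dataclasses.replace(config, lambda_reg=1e-12)
            if observed.all():
                observed[3] = False
            recon = forward_oracle(record.corrupted_input, params)
            base = masked_denoising_loss(x, record, recon, observed, config, params)
            x2 = x.copy()
            x2[~observed] += 10 * rng.standard_normal((~observed).sum())
            # re-corrupting re-zeroes the unobserved inputs at the input layer
            record2 = CorruptionRecord(
                corrupted_input=np.where(observed, x2, 0.0)
                * (~record.corruption_mask(len(x))),
                corrupted_index_set=record.corrupted_index_set,
            )
            recon2 = forward_oracle(record2.corrupted_input, params)
            perturbed = masked_denoising_loss(x2, record2, recon2, observed, config, params)
            assert perturbed == pytest.approx(base, abs=1e-12)


class TestTraining:
    def _w(self, values):
        values = np.asarray(values)
        return FingerprintTargetMatrix(
            values=values,
            bit_ids=tuple(f"fp{k}" for k in range(values.shape[0])),
            target_ids=tuple(f"t{j}" for j in range(values.shape[1])),
            stage="binary",
        )

    def test_single_sample_error_decreases(self, rng):
        x = rng.integers(0, 2, size=12).astype(float)
        x[0] = 1.0
        X = x[None, :]
        config = TrainingConfig(
            hidden_sizes=(4, 2), corruption_rate=0.0, lambda_reg=1e-9,
            epochs=300, learning_rate=1.0, batch_size=1, seed=3,
        )
        result = train_samples(X, config)
        assert result.epoch_losses[-1] < result.epoch_losses[0]

    def test_seeded_determinism(self, fixture_dataset, quick_config):
        W = preprocess(fixture_dataset.Z, fixture_dataset.Y)
        r1 = train(W, quick_config)
        r2 = train(W, quick_config)
        np.testing.assert_array_equal(flatten(r1.params), flatten(r2.params))
        assert r1.epoch_losses == r2.epoch_losses

    def test_monotone_loss_trend(self, fixture_dataset, quick_config):
        W = preprocess(fixture_dataset.Z, fixture_dataset.Y)
        losses = train(W, quick_config).epoch_losses
        k = max(1, len(losses) // 10)
        assert np.mean(losses[-k:]) < np.mean(losses[:k])

    def test_no_observed_interactions_raises(self):
        config = TrainingConfig(hidden_sizes=(2,), epochs=2)
        with pytest.raises(ValueError, match="no observed"):
            train(self._w(np.zeros((4, 3))), config)

    def test_divergence_aborts(self, fixture_dataset):
        W = preprocess(fixture_dataset.Z, fixture_dataset.Y)
        config = TrainingConfig(
            lambda_reg=10.0, learning_rate=1e8, epochs=50, seed=0,
            zeros_are_observed=True,
        )
        with pytest.raises(TrainingDivergedError):
            train(W, config)

    def test_rejects_non_binary_stage(self):
        W = FingerprintTargetMatrix(
            values=np.array([[0.5]]), bit_ids=("a",), target_ids=("t",),
            stage="normalized",
        )
        with pytest.raises(ValueError, match="binary"):
            train(W, TrainingConfig(hidden_sizes=(1,), epochs=1))


class TestReconstruct:
    def test_zero_params_give_half(self):
        W = preprocess(paper_scale_fixture().Z, paper_scale_fixture().Y)
        params = zero_params(200, (15, 5))
        np.testing.assert_allclose(reconstruct(W, params), np.full((200, 26), 0.5))

    def test_columns_equal_decode_encode(self, fixture_dataset, rng):
        W = preprocess(fixture_dataset.Z, fixture_dataset.Y)
        params = initialize_params(200, (15, 5), rng)
        W_hat = reconstruct(W, params)
        assert ((W_hat > 0) & (W_hat < 1)).all()
        for t in (0, 13, 25):
            col = W.values[:, t].astype(float)
            np.testing.assert_allclose(
                W_hat[:, t], decode(encode(col, params), params), atol=1e-12
            )
            np.testing.assert_allclose(W_hat[:, t], forward_oracle(col, params), atol=1e-12)

    def test_dimension_mismatch(self, rng):
        params = initialize_params(10, (4, 2), rng)
        W = FingerprintTargetMatrix(
            values=np.zeros((9, 2)), bit_ids=tuple(f"b{k}" for k in range(9)),
            target_ids=("t0", "t1"), stage="binary",
        )
        with pytest.raises(ValueError):
            reconstruct(W, params)


class TestSerialization:
    def test_round_trip(self, tmp_path, rng):
        params = initialize_params(12, (5, 3), rng)
        save_params(params, tmp_path / "model.npz")
        back = load_params(tmp_path / "model.npz")
        np.testing.assert_array_equal(flatten(params), flatten(back))


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"alpha": 1.5}, {"alpha": 0.0}, {"beta": 1.0}, {"lambda_reg": -1.0},
        {"corruption_rate": 1.0}, {"hidden_sizes": ()}, {"learning_rate": 0.0},
        {"epochs": 0},
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            TrainingConfig(**kwargs)

    def test_defaults(self):
        config = TrainingConfig()
        assert config.alpha == 0.4 and config.beta == 0.6
        assert config.hidden_sizes == (15, 5)
        assert config.batch_size == 100
        assert config.lambda_reg == 10.0
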