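"""Denoising autoencoder with a masked, reweighted reconstruction loss.

Each training sample is one column of the binary fingerprint-target matrix,
i.e. a target's length-f fingerprint profile.  The network is a mirrored
sigmoid stack (f -> 15 -> 5 -> 15 -> f under the defaults).  Training
follows the masked-denoising recipe:

* unknown positions are zero at the input layer and contribute no error and
  no gradient at the output layer;
* a random fraction of the *observed* positions is additionally corrupted
  (zeroed); the squared error on corrupted positions is weighted ``alpha``
  (prediction) and on intact observed positions ``beta`` (reconstruction);
* an L2 penalty ``lambda/2 * sum ||weights||_F^2`` regularises the weight
  matrices (biases optionally).

On binary input, "observed" defaults to the positions equal to 1 — zeros are
treated as missing.  Set ``zeros_are_observed=True`` to treat every position
as known instead.

The network is tiny (hundreds of inputs, two hidden layers) so forward and
backward passes are hand-written dense NumPy; the backward pass is the exact
gradient of :func:`masked_denoising_loss` and is validated against central
finite differences in the test suite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .preprocessing import FingerprintTargetMatrix

__all__ = [
    "TrainingConfig",
    "AutoencoderParams",
    "CorruptionRecord",
    "TrainResult",
    "initialize_params",
    "encode",
    "decode",
    "corrupt",
    "masked_denoising_loss",
    "loss_gradient",
    "train",
    "train_samples",
    "reconstruct",
    "TrainingDivergedError",
]

logger = logging.getLogger(__name__)


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class TrainingConfig:
    """Hyper-parameters of the masked denoising autoencoder.

    Defaults follow the reference configuration: hidden sizes (15, 5),
    minibatch 100, alpha 0.4 / beta 0.6, L2 strength 10 (use 1 for very
    small datasets).  Learning rate, epoch count and corruption rate have no
    published values and are plain defaults.
    """

    alpha: float = 0.4
    beta: float = 0.6
    lambda_reg: float = 10.0
    corruption_rate: float = 0.2
    hidden_sizes: tuple[int, ...] = (15, 5)
    batch_size: int = 100
    epochs: int = 200
    learning_rate: float = 0.1
    seed: int = 0
    zeros_are_observed: bool = False
    regularize_biases: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.beta < 1.0):
            raise ValueError("alpha and beta must lie strictly in (0, 1)")
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        if not (0.0 <= self.corruption_rate < 1.0):
            raise ValueError("corruption_rate must lie in [0, 1)")
        if any(h < 1 for h in self.hidden_sizes) or not self.hidden_sizes:
            raise ValueError("hidden_sizes must be positive integers")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        object.__setattr__(self, "hidden_sizes", tuple(int(h) for h in self.hidden_sizes))


@dataclass
class AutoencoderParams:
    """Mirrored encoder/decoder weights; each weight matrix is (d_in, d_out)."""

    encoder_weights: list[np.ndarray]
    encoder_biases: list[np.ndarray]
    decoder_weights: list[np.ndarray]
    decoder_biases: list[np.ndarray]

    def all_layers(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return list(
            zip(
                self.encoder_weights + self.decoder_weights,
                self.encoder_biases + self.decoder_biases,
            )
        )

    @property
    def input_dim(self) -> int:
        return self.encoder_weights[0].shape[0]

    def validate(self) -> None:
        dim = self.input_dim
        for w, b in self.all_layers():
            if w.shape[0] != dim or b.shape != (w.shape[1],):
                raise ValueError("layer dimensions do not chain")
            if not (np.isfinite(w).all() and np.isfinite(b).all()):
                raise ValueError("non-finite parameter")
            dim = w.shape[1]
        if dim != self.input_dim:
            raise ValueError("decoder does not map back to the input dimension")

    def copy(self) -> "AutoencoderParams":
        return AutoencoderParams(
            [w.copy() for w in self.encoder_weights],
            [b.copy() for b in self.encoder_biases],
            [w.copy() for w in self.decoder_weights],
            [b.copy() for b in self.decoder_biases],
        )


@dataclass(frozen=True)
class CorruptionRecord:
    """A corrupted input vector together with the corrupted position set."""

    corrupted_input: np.ndarray
    corrupted_index_set: frozenset[int]

    def corruption_mask(self, length: int) -> np.ndarray:
        mask = np.zeros(length, dtype=bool)
        if self.corrupted_index_set:
            mask[np.fromiter(self.corrupted_index_set, dtype=int)] = True
        return mask


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def initialize_params(
    input_dim: int,
    hidden_sizes: Sequence[int],
    rng: np.random.Generator,
) -> AutoencoderParams:
    """Seeded uniform init in +-1/sqrt(fan_in); biases start at zero."""
    enc_dims = [input_dim, *hidden_sizes]
    dec_dims = list(reversed(enc_dims))

    def make(dims: list[int]) -> tuple[list[np.ndarray], list[np.ndarray]]:
        weights, biases = [], []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            bound = 1.0 / math.sqrt(d_in)
            weights.append(rng.uniform(-bound, bound, size=(d_in, d_out)))
            biases.append(np.zeros(d_out))
        return weights, biases

    ew, eb = make(enc_dims)
    dw, db = make(dec_dims)
    return AutoencoderParams(ew, eb, dw, db)


def _forward_layers(
    X: np.ndarray, layers: list[tuple[np.ndarray, np.ndarray]]
) -> list[np.ndarray]:
    """Activations for a batch (first entry is the input itself)."""
    acts = [X]
    for w, b in layers:
        acts.append(_sigmoid(acts[-1] @ w + b))
    return acts


def encode(x: np.ndarray, params: AutoencoderParams) -> np.ndarray:
    """Map an input profile to the bottleneck; sigmoid at every layer."""
    x = np.asarray(x, dtype=float)
    layers = list(zip(params.encoder_weights, params.encoder_biases))
    if x.shape[-1] != params.input_dim:
        raise ValueError(f"expected input of length {params.input_dim}, got {x.shape[-1]}")
    return _forward_layers(x, layers)[-1]


def decode(h: np.ndarray, params: AutoencoderParams) -> np.ndarray:
    """Map a bottleneck vector back to a length-f reconstruction in (0, 1)."""
    h = np.asarray(h, dtype=float)
    layers = list(zip(params.decoder_weights, params.decoder_biases))
    if h.shape[-1] != layers[0][0].shape[0]:
        raise ValueError(
            f"expected bottleneck of length {layers[0][0].shape[0]}, got {h.shape[-1]}"
        )
    return _forward_layers(h, layers)[-1]


def corrupt(
    x: np.ndarray,
    observed_mask: np.ndarray,
    rate: float,
    rng: np.random.Generator,
) -> CorruptionRecord:
    """Zero a random subset of the observed positions.

    Each observed position is corrupted independently with probability
    ``rate``, so |C| is Binomial(n_observed, rate).  Unobserved positions are
    zeroed at the input layer and never enter C.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must lie in [0, 1)")
    x = np.asarray(x, dtype=float)
    observed_mask = np.asarray(observed_mask, dtype=bool)
    if x.shape != observed_mask.shape:
        raise ValueError("input and observed mask shapes differ")
    c_mask = observed_mask & (rng.random(x.shape) < rate)
    corrupted = np.where(observed_mask & ~c_mask, x, 0.0)
    return CorruptionRecord(
        corrupted_input=corrupted,
        corrupted_index_set=frozenset(np.flatnonzero(c_mask).tolist()),
    )


def _regularizer(params: AutoencoderParams, config: TrainingConfig) -> float:
    sq = sum(float((w**2).sum()) for w, _ in params.all_layers())
    if config.regularize_biases:
        sq += sum(float((b**2).sum()) for _, b in params.all_layers())
    return 0.5 * config.lambda_reg * sq


def masked_denoising_loss(
    x: np.ndarray,
    record: CorruptionRecord,
    reconstruction: np.ndarray,
    observed_mask: np.ndarray,
    config: TrainingConfig,
    params: AutoencoderParams,
) -> float:
    """alpha-weighted error on corrupted + beta-weighted on intact observed
    positions, plus the L2 weight penalty.  Unobserved positions contribute
    nothing."""
    x = np.asarray(x, dtype=float)
    reconstruction = np.asarray(reconstruction, dtype=float)
    observed_mask = np.asarray(observed_mask, dtype=bool)
    if not (x.shape == reconstruction.shape == observed_mask.shape):
        raise ValueError("vector length mismatch")
    c_mask = record.corruption_mask(x.size)
    sq = (x - reconstruction) ** 2
    data = config.alpha * sq[observed_mask & c_mask].sum() + config.beta * sq[
        observed_mask & ~c_mask
    ].sum()
    return float(data) + _regularizer(params, config)


def _backward(
    acts: list[np.ndarray],
    X_target: np.ndarray,
    weight_map: np.ndarray,
    params: AutoencoderParams,
    config: TrainingConfig,
    batch_scale: float,
) -> AutoencoderParams:
    """Exact gradients of the batch-mean masked loss.

    ``weight_map`` holds the per-position loss weight (alpha on corrupted,
    beta on intact observed, 0 on unobserved); ``acts`` comes from the
    forward pass on the corrupted input.
    """
    layers = params.all_layers()
    R = acts[-1]
    delta = 2.0 * weight_map * (R - X_target) * R * (1.0 - R)
    grads_w: list[np.ndarray] = [None] * len(layers)  # type: ignore[list-item]
    grads_b: list[np.ndarray] = [None] * len(layers)  # type: ignore[list-item]
    for li in range(len(layers) - 1, -1, -1):
        w, _ = layers[li]
        a_prev = acts[li]
        grads_w[li] = batch_scale * (a_prev.T @ delta)
        grads_b[li] = batch_scale * delta.sum(axis=0)
        if li > 0:
            delta = (delta @ w.T) * a_prev * (1.0 - a_prev)
    for li, (w, b) in enumerate(layers):
        grads_w[li] += config.lambda_reg * w
        if config.regularize_biases:
            grads_b[li] += config.lambda_reg * b
    k = len(params.encoder_weights)
    return AutoencoderParams(grads_w[:k], grads_b[:k], grads_w[k:], grads_b[k:])


def loss_gradient(
    x: np.ndarray,
    record: CorruptionRecord,
    observed_mask: np.ndarray,
    config: TrainingConfig,
    params: AutoencoderParams,
) -> AutoencoderParams:
    """Gradient of :func:`masked_denoising_loss` for a single sample."""
    x = np.asarray(x, dtype=float)
    observed_mask = np.asarray(observed_mask, dtype=bool)
    c_mask = record.corruption_mask(x.size)
    weight_map = np.where(
        observed_mask & c_mask,
        config.alpha,
        np.where(observed_mask & ~c_mask, config.beta, 0.0),
    )
    acts = _forward_layers(record.corrupted_input[None, :], params.all_layers())
    return _backward(acts, x[None, :], weight_map[None, :], params, config, 1.0)


@dataclass
class TrainResult:
    params: AutoencoderParams
    epoch_losses: list[float] = field(default_factory=list)


def train_samples(X: np.ndarray, config: TrainingConfig) -> TrainResult:
    """Minibatch gradient descent on a samples x features matrix.

    Every source of randomness (init, shuffling, corruption) comes from one
    generator seeded with ``config.seed``, so runs are bit-reproducible.
    """
    X = np.asarray(X, dtype=float)
    n_samples, n_features = X.shape
    observed = np.ones_like(X, dtype=bool) if config.zeros_are_observed else X > 0
    if not observed.any():
        raise ValueError("no observed interactions: every training position is missing")

    rng = np.random.default_rng(config.seed)
    params = initialize_params(n_features, config.hidden_sizes, rng)
    epoch_losses: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n_samples)
        total = 0.0
        for start in range(0, n_samples, config.batch_size):
            idx = order[start : start + config.batch_size]
            Xb, Ob = X[idx], observed[idx]
            Cb = Ob & (rng.random(Xb.shape) < config.corruption_rate)
            Xcorr = np.where(Ob & ~Cb, Xb, 0.0)
            weight_map = np.where(Cb, config.alpha, np.where(Ob & ~Cb, config.beta, 0.0))

            acts = _forward_layers(Xcorr, params.all_layers())
            diff2 = (acts[-1] - Xb) ** 2
            batch_loss = float((weight_map * diff2).sum()) / len(idx) + _regularizer(
                params, config
            )
            total += batch_loss * len(idx)
            if not np.isfinite(batch_loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}: {batch_loss}"
                )
            grads = _backward(acts, Xb, weight_map, params, config, 1.0 / len(idx))
            for (w, b), (gw, gb) in zip(params.all_layers(), grads.all_layers()):
                w -= config.learning_rate * gw
                b -= config.learning_rate * gb
        epoch_losses.append(total / n_samples)
        if epoch == 0 or (epoch + 1) % max(1, config.epochs // 10) == 0:
            logger.info("epoch %d/%d loss %.6f", epoch + 1, config.epochs, epoch_losses[-1])
    return TrainResult(params=params, epoch_losses=epoch_losses)


def train(W: FingerprintTargetMatrix, config: TrainingConfig) -> TrainResult:
    """Train on the columns of a binary fingerprint-target matrix.

    Each target's length-f fingerprint profile is one sample; the model
    embeds targets in the bottleneck space.
    """
    if W.stage != "binary":
        raise ValueError(f"training expects the binary stage, got {W.stage!r}")
    return train_samples(W.values.T, config)


def train_on_drug_profiles(Y_values: np.ndarray, config: TrainingConfig) -> TrainResult:
    """Ablation variant: rows of the raw interaction matrix as samples."""
    return train_samples(np.asarray(Y_values, dtype=float), config)


def reconstruct(W: FingerprintTargetMatrix, params: AutoencoderParams) -> np.ndarray:
    """Uncorrupted forward pass of every column; entries lie in (0, 1)."""
    if W.values.shape[0] != params.input_dim:
        raise ValueError(
            f"matrix has {W.values.shape[0]} rows but model expects {params.input_dim}"
        )
    acts = _forward_layers(W.values.T.astype(float), params.all_layers())
    return acts[-1].T


def config_with_seed(config: TrainingConfig, seed: int) -> TrainingConfig:
    return replace(config, seed=int(seed))


def save_params(params: AutoencoderParams, path) -> None:
    """Serialize to an .npz container with one named array per layer."""
    arrays: dict[str, np.ndarray] = {}
    for i, (w, b) in enumerate(zip(params.encoder_weights, params.encoder_biases)):
        arrays[f"enc_w{i}"], arrays[f"enc_b{i}"] = w, b
    for i, (w, b) in enumerate(zip(params.decoder_weights, params.decoder_biases)):
        arrays[f"dec_w{i}"], arrays[f"dec_b{i}"] = w, b
    np.savez(path, **arrays)


def load_params(path) -> AutoencoderParams:
    with np.load(path) as data:
        n_enc = sum(1 for k in data.files if k.startswith("enc_w"))
        n_dec = sum(1 for k in data.files if k.startswith("dec_w"))
        params = AutoencoderParams(
            [data[f"enc_w{i}"] for i in range(n_enc)],
            [data[f"enc_b{i}"] for i in range(n_enc)],
            [data[f"dec_w{i}"] for i in range(n_dec)],
            [data[f"dec_b{i}"] for i in range(n_dec)],
        )
    params.validate()
    return params
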