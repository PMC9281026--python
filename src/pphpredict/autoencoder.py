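"""Sparse stacked autoencoder classifier.

Each layer is a sigmoid autoencoder

    h = sigma(W x + b),        x_hat = sigma(W' h + b'),

trained by mini-batch gradient descent on the composite loss

    E = (1/N) sum_i 1/2 ||x_hat_i - x_i||^2
        + (lambda/2) (||W||_F^2 + ||W'||_F^2)
        + beta * KL(rho_hat || rho),

where rho_hat_j is the mean activation of hidden unit j over the batch
and the KL term pushes hidden codes toward the sparsity target rho.
Layers are pretrained greedily — each on the previous layer's hidden
code — then a softmax head is attached to the last code and the encoder
path plus head is fine-tuned end to end on the multinomial cross-entropy.
Decoder weights are frozen after pretraining (configurable).

Inputs are min–max scaled to [0,1] before training, since sigmoid
reconstruction targets require bounded inputs. All randomness flows from
the config seed, so two runs with the same config and data produce
bit-identical models.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import Dataset

__all__ = [
    "SAELayerParams",
    "SAEConfig",
    "SAEModel",
    "sigmoid",
    "encode",
    "decode",
    "kl_sparsity",
    "sparse_ae_loss",
    "sparse_ae_grad",
    "pretrain_layer",
    "stack_and_attach_head",
    "finetune_cost",
    "finetune_grad",
    "finetune",
    "predict",
    "SAEClassifier",
]

_RHO_EPS = 1e-6


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class SAELayerParams:
    """Encoder/decoder parameters of one autoencoder layer."""

    enc_weights: np.ndarray  # (hidden, input)
    enc_bias: np.ndarray  # (hidden,)
    dec_weights: np.ndarray  # (input, hidden)
    dec_bias: np.ndarray  # (input,)

    def __post_init__(self) -> None:
        h, d = self.enc_weights.shape
        if self.enc_bias.shape != (h,) or self.dec_weights.shape != (d, h) or self.dec_bias.shape != (d,):
            raise ValueError("inconsistent layer shapes")
        for a in (self.enc_weights, self.enc_bias, self.dec_weights, self.dec_bias):
            if not np.all(np.isfinite(a)):
                raise ValueError("non-finite layer parameters")

    @property
    def n_hidden(self) -> int:
        return self.enc_weights.shape[0]

    @property
    def n_input(self) -> int:
        return self.enc_weights.shape[1]

    def copy(self) -> "SAELayerParams":
        return SAELayerParams(
            self.enc_weights.copy(), self.enc_bias.copy(),
            self.dec_weights.copy(), self.dec_bias.copy(),
        )


@dataclass(frozen=True)
class SAEConfig:
    """Training hyperparameters of the stacked autoencoder.

    hidden_sizes: width of each stacked layer, outer to inner.
    weight_decay (lambda): L2 penalty on encoder and decoder weights.
    sparsity_weight (beta): weight of the KL sparsity penalty.
    sparsity_target (rho): desired mean hidden activation, small in (0,1).
    init_scale: half-width of the symmetric-uniform weight init; None
    selects sqrt(6 / (fan_in + fan_out)) per layer.
    """

    hidden_sizes: tuple[int, ...] = (32,)
    weight_decay: float = 1e-4
    sparsity_weight: float = 0.1
    sparsity_target: float = 0.1
    learning_rate: float = 0.5
    pretrain_epochs: int = 20
    finetune_epochs: int = 100
    batch_size: int = 32
    init_scale: float | None = None
    full_batch_rho: bool = False
    finetune_decoders: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        hs = tuple(int(h) for h in self.hidden_sizes)
        if len(hs) == 0 or any(h < 1 for h in hs):
            raise ValueError("hidden_sizes must be non-empty positive integers")
        object.__setattr__(self, "hidden_sizes", hs)
        if self.weight_decay < 0 or self.sparsity_weight < 0:
            raise ValueError("weight_decay and sparsity_weight must be non-negative")
        if not 0.0 < self.sparsity_target < 1.0:
            raise ValueError("sparsity_target must lie in (0, 1)")
        if self.learning_rate < 0 or self.batch_size < 1:
            raise ValueError("invalid learning_rate or batch_size")
        if self.pretrain_epochs < 0 or self.finetune_epochs < 0:
            raise ValueError("epoch counts must be non-negative")

    def replace(self, **kw) -> "SAEConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SAEModel:
    """A trained stack of encoder layers plus a softmax head."""

    layers: list[SAELayerParams]
    softmax_weights: np.ndarray  # (n_classes, last hidden)
    softmax_bias: np.ndarray  # (n_classes,)
    n_classes: int
    feature_min: np.ndarray | None = None
    feature_range: np.ndarray | None = None

    def scale(self, X: np.ndarray) -> np.ndarray:
        if self.feature_min is None:
            return X
        return (X - self.feature_min) / self.feature_range

    def hidden_representation(self, X: np.ndarray, scaled: bool = False) -> np.ndarray:
        A = X if scaled else self.scale(X)
        for layer in self.layers:
            A = encode(layer, A)
        return A

    def copy(self) -> "SAEModel":
        return SAEModel(
            [l.copy() for l in self.layers],
            self.softmax_weights.copy(),
            self.softmax_bias.copy(),
            self.n_classes,
            None if self.feature_min is None else self.feature_min.copy(),
            None if self.feature_range is None else self.feature_range.copy(),
        )


def encode(layer: SAELayerParams, inputs: np.ndarray) -> np.ndarray:
    """Hidden code h = sigma(W x + b); rows are samples."""
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    if inputs.shape[1] != layer.n_input:
        raise ValueError(f"expected {layer.n_input} input columns, got {inputs.shape[1]}")
    return sigmoid(inputs @ layer.enc_weights.T + layer.enc_bias)


def decode(layer: SAELayerParams, hidden: np.ndarray) -> np.ndarray:
    """Reconstruction x_hat = sigma(W' h + b')."""
    hidden = np.atleast_2d(np.asarray(hidden, dtype=float))
    if hidden.shape[1] != layer.n_hidden:
        raise ValueError(f"expected {layer.n_hidden} hidden columns, got {hidden.shape[1]}")
    return sigmoid(hidden @ layer.dec_weights.T + layer.dec_bias)


def kl_sparsity(rho_hat: np.ndarray, rho: float) -> float:
    """KL divergence between the target rate rho and each unit's mean
    activation, summed over units (natural log). Zero iff every
    rho_hat_j equals rho; boundary values are an error."""
    rho_hat = np.asarray(rho_hat, dtype=float)
    if not 0.0 < rho < 1.0:
        raise ValueError("rho must lie strictly inside (0, 1)")
    if np.any(rho_hat <= 0.0) or np.any(rho_hat >= 1.0):
        raise ValueError("rho_hat entries must lie strictly inside (0, 1)")
    return float(
        np.sum(rho * np.log(rho / rho_hat) + (1 - rho) * np.log((1 - rho) / (1 - rho_hat)))
    )


def _clipped_rho_hat(H: np.ndarray) -> np.ndarray:
    rho_hat = H.mean(axis=0)
    if np.any(rho_hat <= _RHO_EPS) or np.any(rho_hat >= 1 - _RHO_EPS):
        warnings.warn("mean hidden activation at saturation; clipping for KL term")
    return np.clip(rho_hat, _RHO_EPS, 1 - _RHO_EPS)


def sparse_ae_loss(layer: SAELayerParams, batch: np.ndarray, config: SAEConfig) -> float:
    """Composite autoencoder loss: mean half squared reconstruction
    error + L2 weight decay + KL sparsity penalty on batch-mean hidden
    activations."""
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.shape[0] == 0:
        raise ValueError("empty batch")
    H = encode(layer, batch)
    Xhat = decode(layer, H)
    recon = 0.5 * np.sum((Xhat - batch) ** 2) / batch.shape[0]
    decay = 0.5 * config.weight_decay * (
        np.sum(layer.enc_weights**2) + np.sum(layer.dec_weights**2)
    )
    sparse = 0.0
    if config.sparsity_weight > 0:
        sparse = config.sparsity_weight * kl_sparsity(_clipped_rho_hat(H), config.sparsity_target)
    return float(recon + decay + sparse)


def sparse_ae_grad(
    layer: SAELayerParams, batch: np.ndarray, config: SAEConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradients of :func:`sparse_ae_loss` w.r.t.
    (enc_weights, enc_bias, dec_weights, dec_bias).

    The KL term couples samples through the batch-mean activation
    rho_hat_j; its contribution to d/dh_ij is
    (beta/N) * (-rho/rho_hat_j + (1-rho)/(1-rho_hat_j)).
    """
    X = np.atleast_2d(np.asarray(batch, dtype=float))
    N = X.shape[0]
    H = encode(layer, X)
    Xhat = decode(layer, H)

    delta_out = ((Xhat - X) / N) * Xhat * (1.0 - Xhat)  # (N, d)
    g_dec_w = delta_out.T @ H + config.weight_decay * layer.dec_weights
    g_dec_b = delta_out.sum(axis=0)

    delta_h = delta_out @ layer.dec_weights  # (N, K)
    if config.sparsity_weight > 0:
        rho_hat = _clipped_rho_hat(H)
        rho = config.sparsity_target
        kl_grad = (config.sparsity_weight / N) * (
            -rho / rho_hat + (1.0 - rho) / (1.0 - rho_hat)
        )
        delta_h = delta_h + kl_grad[None, :]
    delta_h = delta_h * H * (1.0 - H)
    g_enc_w = delta_h.T @ X + config.weight_decay * layer.enc_weights
    g_enc_b = delta_h.sum(axis=0)
    return g_enc_w, g_enc_b, g_dec_w, g_dec_b


def _init_layer(n_input: int, n_hidden: int, config: SAEConfig, rng: np.random.Generator) -> SAELayerParams:
    def draw(fan_out: int, fan_in: int) -> np.ndarray:
        scale = config.init_scale
        if scale is None:
            scale = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-scale, scale, size=(fan_out, fan_in))

    return SAELayerParams(
        enc_weights=draw(n_hidden, n_input),
        enc_bias=np.zeros(n_hidden),
        dec_weights=draw(n_input, n_hidden),
        dec_bias=np.zeros(n_input),
    )


class TrainingDivergence(RuntimeError):
    """Raised when the loss becomes non-finite; carries the epoch index."""

    def __init__(self, epoch: int):
        super().__init__(f"training diverged at epoch {epoch}")
        self.epoch = epoch


def pretrain_layer(
    inputs: np.ndarray,
    hidden_size: int,
    config: SAEConfig,
    rng: np.random.Generator,
) -> tuple[SAELayerParams, np.ndarray]:
    """Train one sparse autoencoder layer by mini-batch gradient descent.

    Returns the trained layer and the per-epoch full-data loss trace
    (length pretrain_epochs + 1, including the initial loss).
    """
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    n = X.shape[0]
    layer = _init_layer(X.shape[1], hidden_size, config, rng)
    losses = [sparse_ae_loss(layer, X, config)]
    batch = n if config.full_batch_rho else min(config.batch_size, n)
    for epoch in range(config.pretrain_epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            gw, gb, gdw, gdb = sparse_ae_grad(layer, X[idx], config)
            layer.enc_weights -= config.learning_rate * gw
            layer.enc_bias -= config.learning_rate * gb
            layer.dec_weights -= config.learning_rate * gdw
            layer.dec_bias -= config.learning_rate * gdb
        loss = sparse_ae_loss(layer, X, config)
        if not np.isfinite(loss):
            raise TrainingDivergence(epoch)
        losses.append(loss)
    return layer, np.asarray(losses)


def stack_and_attach_head(
    dataset: Dataset, config: SAEConfig, n_classes: int = 2
) -> SAEModel:
    """Greedy layer-wise pretraining followed by softmax-head attachment.

    Layer l+1 is pretrained on the hidden code of layer l. Features are
    min–max scaled to [0,1] first; the scaler is stored on the model.
    The softmax head starts at zero (uniform probabilities) and is
    trained during :func:`finetune`.
    """
    rng = np.random.default_rng(config.seed)
    X = np.asarray(dataset.features, dtype=float)
    fmin = X.min(axis=0)
    frange = X.max(axis=0) - fmin
    frange[frange == 0] = 1.0
    A = (X - fmin) / frange
    layers: list[SAELayerParams] = []
    for h in config.hidden_sizes:
        layer, _ = pretrain_layer(A, h, config, rng)
        layers.append(layer)
        A = encode(layer, A)
    return SAEModel(
        layers=layers,
        softmax_weights=np.zeros((n_classes, config.hidden_sizes[-1])),
        softmax_bias=np.zeros(n_classes),
        n_classes=n_classes,
        feature_min=fmin,
        feature_range=frange,
    )


def _forward(model: SAEModel, X: np.ndarray, scaled: bool = False) -> tuple[list[np.ndarray], np.ndarray]:
    """Activations per layer (input first) and class logits."""
    A = X if scaled else model.scale(X)
    acts = [A]
    for layer in model.layers:
        A = encode(layer, A)
        acts.append(A)
    logits = A @ model.softmax_weights.T + model.softmax_bias
    return acts, logits


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=1, keepdims=True)
    z = logits - m
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


def finetune_cost(
    model: SAEModel, batch: np.ndarray, labels: np.ndarray, scaled: bool = False
) -> float:
    """Multinomial cross-entropy of the encoder path + softmax head,
    computed with a log-sum-exp for numerical safety."""
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 0 or labels.max() >= model.n_classes:
        raise ValueError("label out of range")
    _, logits = _forward(model, np.atleast_2d(batch), scaled=scaled)
    logp = _log_softmax(logits)
    return float(-logp[np.arange(labels.size), labels].mean())


def finetune_grad(
    model: SAEModel, batch: np.ndarray, labels: np.ndarray, scaled: bool = False
) -> dict:
    """Analytic gradients of :func:`finetune_cost` w.r.t. the softmax
    head and every encoder layer (decoders are not part of this path)."""
    labels = np.asarray(labels, dtype=int)
    X = np.atleast_2d(batch)
    acts, logits = _forward(model, X, scaled=scaled)
    m = labels.size
    P = np.exp(_log_softmax(logits))
    Y = np.zeros_like(P)
    Y[np.arange(m), labels] = 1.0
    dZ = (P - Y) / m
    grads = {
        "softmax_weights": dZ.T @ acts[-1],
        "softmax_bias": dZ.sum(axis=0),
        "layers": [],
    }
    dA = dZ @ model.softmax_weights
    for l in range(len(model.layers) - 1, -1, -1):
        H = acts[l + 1]
        d_pre = dA * H * (1.0 - H)
        grads["layers"].append(
            {"enc_weights": d_pre.T @ acts[l], "enc_bias": d_pre.sum(axis=0)}
        )
        dA = d_pre @ model.layers[l].enc_weights
    grads["layers"].reverse()
    return grads


def finetune(
    model: SAEModel,
    dataset: Dataset,
    config: SAEConfig,
    rng: np.random.Generator,
) -> tuple[SAEModel, np.ndarray]:
    """Fine-tune the encoder stack and softmax head by mini-batch
    backpropagation on the cross-entropy; decoders stay frozen. Returns
    the tuned model and the per-epoch full-data cost trace."""
    model = model.copy()
    X = model.scale(np.asarray(dataset.features, dtype=float))
    y = dataset.labels
    n = X.shape[0]
    costs = [finetune_cost(model, X, y, scaled=True)]
    batch = min(config.batch_size, n)
    for epoch in range(config.finetune_epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            g = finetune_grad(model, X[idx], y[idx], scaled=True)
            model.softmax_weights -= config.learning_rate * g["softmax_weights"]
            model.softmax_bias -= config.learning_rate * g["softmax_bias"]
            for layer, gl in zip(model.layers, g["layers"]):
                layer.enc_weights -= config.learning_rate * gl["enc_weights"]
                layer.enc_bias -= config.learning_rate * gl["enc_bias"]
        cost = finetune_cost(model, X, y, scaled=True)
        if not np.isfinite(cost):
            raise TrainingDivergence(epoch)
        costs.append(cost)
    return model, np.asarray(costs)


def predict(model: SAEModel, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and hard labels (argmax, ties to the lower
    class index)."""
    _, logits = _forward(model, np.atleast_2d(features))
    P = np.exp(_log_softmax(logits))
    return P, P.argmax(axis=1)


class SAEClassifier:
    """Scikit-learn-style wrapper: scale, pretrain, fine-tune, predict."""

    def __init__(self, config: SAEConfig):
        self.config = config
        self.model_: SAEModel | None = None
        self.finetune_costs_: np.ndarray | None = None

    def fit(self, dataset: Dataset) -> "SAEClassifier":
        model = stack_and_attach_head(dataset, self.config)
        rng = np.random.default_rng(self.config.seed + 1)
        self.model_, self.finetune_costs_ = finetune(model, dataset, self.config, rng)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        assert self.model_ is not None, "call fit first"
        return predict(self.model_, X)[0]

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        assert self.model_ is not None, "call fit first"
        return predict(self.model_, X)[1]

    def score(self, dataset: Dataset) -> float:
        return float((self.predict_labels(dataset.features) == dataset.labels).mean())
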