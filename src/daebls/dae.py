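"""Denoising autoencoder feature extraction.

A single-hidden-layer autoencoder is trained to reconstruct the clean input
M from a deliberately corrupted version: the encoder P = f(theta M~ + beta)
maps the corrupted matrix to a hidden representation, a linear decoder maps
it back, and mini-batch gradient descent minimizes the mean squared
reconstruction error against the *clean* input. Corruption (additive Gaussian
noise or random masking) is a training-only device: encoding at inference
time is a pure deterministic function of (model, data). Several independently
trained DAEs, concatenated, form the mapped-feature layer T^n of the broad
learning system.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .errors import ConfigError, NumericError, SchemaError

_ACTIVATIONS = {
    "sigmoid": (expit, lambda a: a * (1.0 - a)),
    "tanh": (np.tanh, lambda a: 1.0 - a**2),
    "linear": (lambda z: z, lambda a: np.ones_like(a)),
}


def activation_fn(name: str):
    try:
        return _ACTIVATIONS[name][0]
    except KeyError:
        raise ConfigError(f"unknown activation {name!r}") from None


@dataclass(frozen=True)
class CorruptionSpec:
    """How training inputs are damaged: additive Gaussian (level = SD in
    standardized units) or masking (level = fraction of cells zeroed)."""

    kind: str = "gaussian_additive"
    level: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian_additive", "masking"):
            raise ConfigError(f"unknown corruption kind {self.kind!r}")
        if self.level < 0:
            raise ConfigError("corruption level must be nonnegative")
        if self.kind == "masking" and self.level > 1:
            raise ConfigError("masking level must lie in [0, 1]")


def corrupt(data: np.ndarray, spec: CorruptionSpec) -> np.ndarray:
    """Return a damaged copy of ``data``; the input is never modified."""
    data = np.asarray(data, dtype=float)
    rng = np.random.default_rng(spec.seed)
    if spec.level == 0:
        return data.copy()
    if spec.kind == "gaussian_additive":
        return data + rng.normal(0.0, spec.level, size=data.shape)
    keep = rng.random(data.shape) >= spec.level
    return data * keep


@dataclass(frozen=True)
class DAEConfig:
    epochs: int = 100
    learning_rate: float = 0.01
    batch_size: int = 32
    activation: str = "sigmoid"
    corruption_kind: str = "gaussian_additive"
    corruption_level: float = 0.1
    seed: int = 0


@dataclass
class DAEModel:
    """Encoder (theta, beta), linear decoder, and the training trace."""

    encoder_weights: np.ndarray  # d x h  (theta)
    encoder_bias: np.ndarray  # h      (beta)
    decoder_weights: np.ndarray  # h x d
    decoder_bias: np.ndarray  # d
    activation: str = "sigmoid"
    corruption: CorruptionSpec = field(default_factory=CorruptionSpec)
    training_log: list[float] = field(default_factory=list)

    @property
    def input_dim(self) -> int:
        return self.encoder_weights.shape[0]

    @property
    def hidden_width(self) -> int:
        return self.encoder_weights.shape[1]


def encode(model: DAEModel, data: np.ndarray) -> np.ndarray:
    """f(data . theta + beta). No corruption is ever applied at inference."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != model.input_dim:
        raise SchemaError(
            f"expected {model.input_dim} feature columns, got shape {data.shape}"
        )
    f = activation_fn(model.activation)
    return f(data @ model.encoder_weights + model.encoder_bias)


def _decode(model: DAEModel, hidden: np.ndarray) -> np.ndarray:
    return hidden @ model.decoder_weights + model.decoder_bias


def reconstruction_error(model: DAEModel, data: np.ndarray) -> float:
    """Mean squared clean-input reconstruction error."""
    return float(np.mean((_decode(model, encode(model, data)) - data) ** 2))


def _init_model(d: int, h: int, config: DAEConfig, rng: np.random.Generator) -> DAEModel:
    s_enc = np.sqrt(6.0 / (d + h))
    return DAEModel(
        encoder_weights=rng.uniform(-s_enc, s_enc, size=(d, h)),
        encoder_bias=np.zeros(h),
        decoder_weights=rng.uniform(-s_enc, s_enc, size=(h, d)),
        decoder_bias=np.zeros(d),
        activation=config.activation,
        corruption=CorruptionSpec(config.corruption_kind, config.corruption_level,
                                  seed=int(rng.integers(2**31))),
    )


def train_dae(data: np.ndarray, hidden_width: int, config: DAEConfig = DAEConfig()) -> DAEModel:
    """Mini-batch gradient descent on ||decode(encode(corrupt(M))) - M||^2.

    A fresh corruption draw is taken every epoch; the returned parameters are
    the best snapshot by clean reconstruction error, so the final error never
    exceeds the initial one. Deterministic given ``config.seed``.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ConfigError("training data must be a 2-D matrix with >= 2 rows")
    if hidden_width < 1:
        raise ConfigError("hidden_width must be a positive integer")
    n, d = data.shape
    rng = np.random.default_rng(config.seed)
    model = _init_model(d, hidden_width, config, rng)
    if config.epochs == 0:
        return model

    f, fprime = _ACTIVATIONS[config.activation]
    W1, b1 = model.encoder_weights.copy(), model.encoder_bias.copy()
    W2, b2 = model.decoder_weights.copy(), model.decoder_bias.copy()
    lr = config.learning_rate
    best_err = np.inf
    best = (W1.copy(), b1.copy(), W2.copy(), b2.copy())
    log: list[float] = []

    for _ in range(config.epochs):
        noisy = corrupt(data, replace(model.corruption, seed=int(rng.integers(2**31))))
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            Mc, M = noisy[idx], data[idx]
            P = f(Mc @ W1 + b1)
            R = P @ W2 + b2
            err = R - M
            if not np.isfinite(err).all():
                raise NumericError(
                    "training loss diverged; reduce the learning rate"
                )
            scale = 2.0 / err.size
            dR = scale * err
            gW2 = P.T @ dR
            gb2 = dR.sum(axis=0)
            dP = dR @ W2.T
            dZ = dP * fprime(P)
            gW1 = Mc.T @ dZ
            gb1 = dZ.sum(axis=0)
            W1 -= lr * gW1
            b1 -= lr * gb1
            W2 -= lr * gW2
            b2 -= lr * gb2
        snapshot = DAEModel(W1, b1, W2, b2, config.activation, model.corruption)
        epoch_err = reconstruction_error(snapshot, data)
        log.append(epoch_err)
        if epoch_err < best_err:
            best_err = epoch_err
            best = (W1.copy(), b1.copy(), W2.copy(), b2.copy())

    return DAEModel(*best, activation=config.activation,
                    corruption=model.corruption, training_log=log)


def build_mapping_layer(
    data: np.ndarray,
    n_groups: int,
    hidden_width: int,
    config: DAEConfig = DAEConfig(),
) -> tuple[list[DAEModel], np.ndarray]:
    """Train ``n_groups`` DAEs with distinct seeds and concatenate their
    encodings into the mapped-feature matrix T^n (n_samples x n_groups*hidden)."""
    if n_groups < 1:
        raise ConfigError("n_groups must be a positive integer")
    models = []
    for g in range(n_groups):
        seed = int(np.random.SeedSequence(config.seed, spawn_key=(0, g)).generate_state(1)[0] % 2**31)
        models.append(train_dae(data, hidden_width, replace(config, seed=seed)))
    Tn = np.hstack([encode(m, data) for m in models])
    return models, Tn
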