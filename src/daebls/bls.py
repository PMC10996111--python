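"""Broad learning system core: enhancement layer, ridge output weights, prediction.

The hidden state is A = [T^n | H^m]: the DAE mapped-feature block T^n next to
m groups of enhancement nodes H_j = xi(T^n W_hj + beta_hj) whose weights are
drawn uniform on [-1, 1] once and never updated. The only learned parameters
are the output weights W solving the ridge problem

    min_W ||A W - Y||^2 + lambda ||W||^2   =>   W = (A'A + lambda I)^-1 A' Y,

with Y a one-hot encoding of the class labels (sorted order) and the decision
rule argmax over per-class scores. With the default lambda = 1e-8 the ridge
pseudoinverse A+ = (A'A + lambda I)^-1 A' is numerically the Moore-Penrose
pseudoinverse on well-conditioned inputs; A, A+ and the one-hot Y are cached
on the model so enhancement nodes can later be appended incrementally.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .dae import DAEConfig, DAEModel, activation_fn, build_mapping_layer, encode
from .errors import ConfigError, DataError, NumericError, SchemaError
from .table import FeatureTable

DEFAULT_LAMBDA = 1e-10


# ---------------------------------------------------------------------------
# enhancement groups
# ---------------------------------------------------------------------------
@dataclass
class EnhancementGroup:
    """Fixed random projection: weights (inputs x p), bias (p), activation xi.

    ``scale`` is the standard BLS shrink factor applied to the projection
    before the bias, H = xi(scale * T^n W + beta): with many mapped-feature
    inputs an unscaled uniform[-1, 1] projection saturates tanh and collapses
    the enhancement block's spectrum. Fitting uses 1/sqrt(n_inputs); the
    default 1 leaves the plain projection untouched.
    """

    weights: np.ndarray
    bias: np.ndarray
    activation: str = "tanh"
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.weights.ndim != 2 or self.bias.shape != (self.weights.shape[1],):
            raise SchemaError("weights must be 2-D with one bias per output node")
        self.weights.setflags(write=False)
        self.bias.setflags(write=False)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[1]


def make_enhancement_group(
    n_inputs: int, p: int, activation: str = "tanh", seed: int = 0,
    scale: float = 1.0,
) -> EnhancementGroup:
    """Draw weights and bias i.i.d. uniform on [-1, 1]; immutable thereafter."""
    if p < 1:
        raise ConfigError("p must be a positive integer")
    if n_inputs < 1:
        raise ConfigError("n_inputs must be a positive integer")
    rng = np.random.default_rng(seed)
    return EnhancementGroup(
        weights=rng.uniform(-1.0, 1.0, size=(n_inputs, p)),
        bias=rng.uniform(-1.0, 1.0, size=p),
        activation=activation,
        scale=scale,
    )


def enhance(Tn: np.ndarray, group: EnhancementGroup) -> np.ndarray:
    """H_j = xi(T^n W_hj + beta_hj)."""
    Tn = np.asarray(Tn, dtype=float)
    if Tn.ndim != 2 or Tn.shape[1] != group.weights.shape[0]:
        raise SchemaError(
            f"mapped features have {Tn.shape[1] if Tn.ndim == 2 else '?'} columns, "
            f"group expects {group.weights.shape[0]}"
        )
    return activation_fn(group.activation)(
        group.scale * (Tn @ group.weights) + group.bias
    )


# ---------------------------------------------------------------------------
# ridge solves
# ---------------------------------------------------------------------------
def ridge_solve(A: np.ndarray, Y: np.ndarray, lam: float) -> np.ndarray:
    """W = (A'A + lambda I)^-1 A'Y via a symmetric positive-definite solve."""
    A = np.asarray(A, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if lam <= 0:
        raise ConfigError("lam must be positive")
    if A.shape[0] != Y.shape[0]:
        raise SchemaError("A and Y must have equal row counts")
    if not (np.isfinite(A).all() and np.isfinite(Y).all()):
        raise NumericError("non-finite entries in the ridge system")
    G = A.T @ A + lam * np.eye(A.shape[1])
    W = scipy.linalg.solve(G, A.T @ Y, assume_a="pos")
    if not np.isfinite(W).all():
        raise NumericError("ridge solution is non-finite")
    return W


def pinv_ridge(A: np.ndarray, lam: float = DEFAULT_LAMBDA) -> np.ndarray:
    """Ridge-regularized pseudoinverse A+ = (A'A + lambda I)^-1 A'.

    Converges to the Moore-Penrose pseudoinverse as lambda -> 0; at the
    default lambda it satisfies the four Moore-Penrose conditions to ~1e-5 on
    well-conditioned inputs.
    """
    A = np.asarray(A, dtype=float)
    return ridge_solve(A, np.eye(A.shape[0]), lam)


def one_hot(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """{0,1} indicator matrix with columns in the fixed class order."""
    Y = np.zeros((len(y), len(classes)))
    for c, cls in enumerate(classes):
        Y[y == cls, c] = 1.0
    return Y


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class BLSConfig:
    """Architecture and solver settings.

    enhancement_groups lists the node count of each enhancement group (the
    common single-group case is e.g. [1000]); every random draw is derived
    deterministically from ``seed``.
    """

    n_mapping_groups: int = 10
    mapping_hidden: int = 10
    enhancement_groups: tuple[int, ...] = (1000,)
    enhancement_activation: str = "tanh"
    ridge_lambda: float = DEFAULT_LAMBDA
    dae: DAEConfig = field(default_factory=DAEConfig)
    seed: int = 0


def enhancement_seed(base_seed: int, group_index: int) -> int:
    """Deterministic per-group seed; increments reuse the same stream."""
    ss = np.random.SeedSequence(base_seed, spawn_key=(1, group_index))
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class BLSModel:
    mapping: list[DAEModel]
    groups: list[EnhancementGroup]
    ridge_lambda: float
    classes: np.ndarray
    W: np.ndarray
    A: np.ndarray = field(repr=False)
    A_pinv: np.ndarray = field(repr=False)
    Tn_cache: np.ndarray = field(repr=False)
    Y_cache: np.ndarray = field(repr=False)
    config: BLSConfig | None = None
    feature_names: list[str] | None = None

    @property
    def n_enhancement_nodes(self) -> int:
        return sum(g.n_nodes for g in self.groups)

    def mapped_features(self, X: np.ndarray) -> np.ndarray:
        return np.hstack([encode(m, X) for m in self.mapping])

    def hidden_state(self, X: np.ndarray) -> np.ndarray:
        Tn = self.mapped_features(X)
        H = [enhance(Tn, g) for g in self.groups]
        return np.hstack([Tn, *H])


def fit(train: FeatureTable, config: BLSConfig = BLSConfig()) -> BLSModel:
    """Train DAE-BLS on a preprocessed (complete, standardized) table.

    Builds the DAE mapping layer, draws the enhancement groups, forms
    A = [T^n | H^m] and solves W = A+ Y in one step — only W is learned.
    """
    if train.y is None:
        raise DataError("training table must carry labels")
    if train.n_missing() > 0:
        raise DataError("training table has missing cells; preprocess first")
    y = train.labels()
    classes = np.unique(y)
    if len(classes) < 2:
        raise DataError("training data contains a single class")
    if train.n_samples < len(classes):
        raise DataError("fewer rows than classes")

    X = train.features()
    mapping, Tn = build_mapping_layer(
        X, config.n_mapping_groups, config.mapping_hidden,
        dataclasses.replace(config.dae, seed=config.seed),
    )
    groups = [
        make_enhancement_group(
            Tn.shape[1], p, config.enhancement_activation,
            seed=enhancement_seed(config.seed, i),
            scale=1.0 / np.sqrt(Tn.shape[1]),
        )
        for i, p in enumerate(config.enhancement_groups)
    ]
    A = np.hstack([Tn, *[enhance(Tn, g) for g in groups]])
    Y = one_hot(y, classes)
    A_pinv = pinv_ridge(A, config.ridge_lambda)
    W = A_pinv @ Y
    return BLSModel(
        mapping=mapping, groups=groups, ridge_lambda=config.ridge_lambda,
        classes=classes, W=W, A=A, A_pinv=A_pinv, Tn_cache=Tn, Y_cache=Y,
        config=config, feature_names=train.feature_names,
    )


def decision_scores(model: BLSModel, data: FeatureTable | np.ndarray) -> np.ndarray:
    if isinstance(data, FeatureTable):
        if model.feature_names is not None and data.feature_names != model.feature_names:
            raise SchemaError("feature names differ from the training schema")
        if data.n_missing() > 0:
            raise DataError("prediction input has missing cells; preprocess first")
        X = data.features()
    else:
        X = np.asarray(data, dtype=float)
    return model.hidden_state(X) @ model.W


def predict(
    model: BLSModel, data: FeatureTable | np.ndarray, return_scores: bool = False
):
    """Argmax over per-class scores; ties resolve to the first class in order."""
    scores = decision_scores(model, data)
    labels = model.classes[np.argmax(scores, axis=1)]
    return (labels, scores) if return_scores else labels
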