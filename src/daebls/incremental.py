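"""Incremental enhancement-node addition without retraining.

When a fitted broad learning system is not accurate enough, a new group of
enhancement nodes H_new = xi(T^n W_new + beta_new) is appended to the hidden
state, A -> A_new = [A | H_new], and the pseudoinverse and output weights are
updated by a Greville-style block formula instead of refitting:

    D  = A+ H_new
    C  = H_new - A D                     (component of H_new outside col(A))
    B' = C+                              if C != 0
    B' = (I + D'D)^-1 D' A+              if C == 0
    A_new+ = [A+ - D B' ; B']
    W_new  = [W - D B'Y ; B'Y]

The C == 0 branch covers new nodes that are linear combinations of existing
hidden columns. A from-scratch retrain oracle (SVD pseudoinverse, no code
shared with the update path) is provided for equivalence testing, and
``increment_experiment`` reproduces the increment-vs-retrain benchmark
design: same random draws, compare accuracy and wall time.
"""

from __future__ import annotations

import copy
import logging
import time
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .bls import (
    BLSConfig,
    BLSModel,
    EnhancementGroup,
    enhance,
    enhancement_seed,
    fit,
    make_enhancement_group,
    pinv_ridge,
    predict,
)
from .errors import ConfigError, DataError
from .table import FeatureTable

logger = logging.getLogger(__name__)

# relative Frobenius threshold deciding the C == 0 branch
C_ZERO_RTOL = 1e-10


@dataclass
class IncrementResult:
    """All intermediates of one block update (kept for inspection/testing)."""

    H_new: np.ndarray
    D: np.ndarray
    C: np.ndarray
    B_T: np.ndarray
    A_new: np.ndarray
    A_new_pinv: np.ndarray
    W_new: np.ndarray
    branch: str  # "C_nonzero" | "C_zero"


def augment_pinv(
    A: np.ndarray,
    A_pinv: np.ndarray,
    W: np.ndarray,
    Y: np.ndarray,
    H_new: np.ndarray,
    lam: float,
) -> IncrementResult:
    """Apply the block pseudoinverse / weight update for appended columns."""
    if H_new.shape[0] != A.shape[0]:
        raise DataError("H_new must have the same row count as A")
    D = A_pinv @ H_new
    C = H_new - A @ D
    c_norm = np.linalg.norm(C)
    tol = C_ZERO_RTOL * max(1.0, np.linalg.norm(H_new))
    if c_norm > tol:
        branch = "C_nonzero"
        B_T = pinv_ridge(C, lam)
    else:
        branch = "C_zero"
        p = D.shape[1]
        B_T = scipy.linalg.solve(
            np.eye(p) + D.T @ D, D.T @ A_pinv, assume_a="pos"
        )
    if abs(c_norm - tol) < 10 * tol:
        logger.info("||C||_F = %.3e near branch tolerance %.3e; took %s",
                    c_norm, tol, branch)
    BY = B_T @ Y
    A_new = np.hstack([A, H_new])
    A_new_pinv = np.vstack([A_pinv - D @ B_T, B_T])
    W_new = np.vstack([W - D @ BY, BY])
    return IncrementResult(H_new, D, C, B_T, A_new, A_new_pinv, W_new, branch)


def add_enhancement_nodes(
    model: BLSModel, p: int, seed: int | None = None
) -> BLSModel:
    """Append a fresh enhancement group of ``p`` nodes and update (A, A+, W).

    The new weights/bias are uniform on [-1, 1]; when ``seed`` is omitted it
    is derived from the model's base seed and the next group index, so an
    incremented model and a model fitted from scratch with the extra group in
    its architecture use identical draws. The input model is left untouched.
    """
    if p < 1:
        raise ConfigError("p must be a positive integer (no-op increments rejected)")
    if model.A is None or model.A_pinv is None or model.Y_cache is None:
        raise DataError("model lacks cached training state; refit from scratch")
    if seed is None:
        if model.config is None:
            raise DataError("model carries no base seed; pass seed explicitly")
        seed = enhancement_seed(model.config.seed, len(model.groups))
    n_inputs = model.Tn_cache.shape[1]
    group = make_enhancement_group(
        n_inputs, p,
        model.groups[0].activation if model.groups else "tanh",
        seed=seed,
        scale=model.groups[0].scale if model.groups else 1.0 / np.sqrt(n_inputs),
    )
    H_new = enhance(model.Tn_cache, group)
    res = augment_pinv(model.A, model.A_pinv, model.W, model.Y_cache,
                       H_new, model.ridge_lambda)
    logger.info("added %d enhancement nodes (branch %s)", p, res.branch)
    new = copy.copy(model)
    new.groups = [*model.groups, group]
    new.A, new.A_pinv, new.W = res.A_new, res.A_new_pinv, res.W_new
    return new


def retrain_oracle(model: BLSModel, new_group: EnhancementGroup) -> np.ndarray:
    """From-scratch output weights pinv([A | H_new]) Y via SVD.

    Deliberately shares no solver code with the incremental path; used as the
    independent reference in equivalence tests.
    """
    H_new = enhance(model.Tn_cache, new_group)
    A_new = np.hstack([model.A, H_new])
    return np.linalg.pinv(A_new) @ model.Y_cache


def increment_experiment(
    train: FeatureTable,
    test: FeatureTable,
    start_nodes: int,
    added_nodes: int,
    config: BLSConfig | None = None,
) -> dict:
    """Fit, increment, and compare against retraining with identical draws.

    Fits a model with ``start_nodes`` enhancement nodes, appends
    ``added_nodes`` by the block update, and separately fits a fresh model
    whose architecture already contains both groups (same derived seeds, so
    its hidden matrix is bit-identical). Reports both test accuracies, their
    gap, weight agreement and wall times.
    """
    if added_nodes < 1:
        raise ConfigError("added_nodes must be >= 1")
    if start_nodes < 1:
        raise ConfigError("start_nodes must be >= 1")
    cfg = config or BLSConfig()
    cfg = _with_groups(cfg, (start_nodes,))

    from .metrics import accuracy  # local import to avoid a cycle

    t0 = time.perf_counter()
    base = fit(train, cfg)
    t_fit = time.perf_counter() - t0
    acc0 = accuracy(test.labels(), predict(base, test))

    t0 = time.perf_counter()
    inc = add_enhancement_nodes(base, added_nodes)
    t_inc = time.perf_counter() - t0
    pred_inc = predict(inc, test)
    acc_inc = accuracy(test.labels(), pred_inc)

    t0 = time.perf_counter()
    retrained = fit(train, _with_groups(cfg, (start_nodes, added_nodes)))
    t_retrain = time.perf_counter() - t0
    pred_re = predict(retrained, test)
    acc_re = accuracy(test.labels(), pred_re)

    w_rel_err = float(
        np.linalg.norm(inc.W - retrained.W) / max(np.linalg.norm(retrained.W), 1e-300)
    )
    return {
        "start_nodes": start_nodes,
        "added_nodes": added_nodes,
        "test_accuracy_start": acc0,
        "test_accuracy_incremented": acc_inc,
        "test_accuracy_retrained": acc_re,
        "accuracy_gap_pp": abs(acc_inc - acc_re),
        "label_agreement_pct": 100.0 * float(np.mean(pred_inc == pred_re)),
        "weight_rel_err": w_rel_err,
        "time_fit_s": t_fit,
        "time_increment_s": t_inc,
        "time_retrain_s": t_retrain,
        "train_accuracy_incremented": accuracy(train.labels(), predict(inc, train)),
        "train_accuracy_retrained": accuracy(train.labels(), predict(retrained, train)),
    }


def _with_groups(cfg: BLSConfig, groups: tuple[int, ...]) -> BLSConfig:
    import dataclasses

    return dataclasses.replace(cfg, enhancement_groups=groups)
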