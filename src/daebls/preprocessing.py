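"""Preprocessing pipeline: KNN imputation -> z-score standardization -> SMOTE.

The three stages mirror how clinical tables are usually cleaned before a
classifier sees them: fill missing cells from the k nearest complete-enough
neighbours, remove per-feature scale (z-score, population SD so the fitting
set comes out exactly mean 0 / SD 1), and rebalance the minority class by
interpolating new minority rows (SMOTE). All stages follow fit-on-train /
apply-to-test semantics; SMOTE is applied to training data only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .errors import ConfigError, DataError, SchemaError
from .table import FeatureTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# z-score standardization: x* = (x - mu) / sigma
# ---------------------------------------------------------------------------
@dataclass
class ScalerParams:
    """Per-feature mean mu and population standard deviation sigma."""

    mu: np.ndarray
    sigma: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        if len(self.mu) != len(self.sigma) or len(self.mu) != len(self.feature_names):
            raise SchemaError("one (mu, sigma) pair per feature required")
        if np.any(self.sigma < 0):
            raise DataError("sigma must be nonnegative")


def zscore_fit(table: FeatureTable) -> ScalerParams:
    """Fit mu / sigma per feature. Requires a complete table with >= 2 rows."""
    if table.n_missing() > 0:
        raise DataError("table contains missing cells; impute before standardizing")
    if table.n_samples < 2:
        raise DataError("need at least 2 rows to fit a scaler")
    X = table.features()
    return ScalerParams(X.mean(axis=0), X.std(axis=0, ddof=0), table.feature_names)


def zscore_transform(table: FeatureTable, params: ScalerParams) -> FeatureTable:
    """Apply (x - mu) / sigma cell-wise; constant features (sigma = 0) map to 0."""
    if table.feature_names != params.feature_names:
        raise SchemaError(
            "feature names differ from those the scaler was fitted on: "
            f"{table.feature_names} vs {params.feature_names}"
        )
    X = table.features()
    sigma = params.sigma.copy()
    degenerate = sigma == 0
    if degenerate.any():
        logger.warning("constant features mapped to 0: %s",
                       [n for n, d in zip(params.feature_names, degenerate) if d])
        sigma[degenerate] = 1.0
    Z = (X - params.mu) / sigma
    Z[:, degenerate] = 0.0
    out = pd.DataFrame(Z, columns=table.feature_names)
    # preserve the missing mask if the input still had holes
    out[table.X.isna().to_numpy()] = np.nan
    return FeatureTable(out, None if table.y is None else table.y.copy())


# ---------------------------------------------------------------------------
# KNN missing-value imputation
# ---------------------------------------------------------------------------
@dataclass
class ImputerParams:
    """k nearest reference rows; distance = Euclidean over co-observed features,
    normalized by the number of co-observed features."""

    k: int
    reference_table: FeatureTable = field(repr=False)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigError("k must be a positive integer")
        if self.k > self.reference_table.n_samples:
            raise ConfigError("k exceeds the number of reference rows")


def fit_imputer(reference: FeatureTable, k: int = 5) -> ImputerParams:
    return ImputerParams(k=k, reference_table=reference.copy())


def _nan_distances(row: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Mean-normalized Euclidean distance over co-observed features; NaN-safe."""
    obs = ~np.isnan(row) & ~np.isnan(ref)
    n_obs = obs.sum(axis=1)
    diff = np.where(obs, ref - row, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = (diff**2).sum(axis=1) / n_obs
    d2[n_obs == 0] = np.inf
    return np.sqrt(d2)


def knn_impute(table: FeatureTable, params: ImputerParams) -> FeatureTable:
    """Fill every missing cell with the unweighted mean of the feature over the
    k nearest reference rows that observe it.

    Falls back to the feature's global reference mean (with a warning) when
    fewer than k reference rows observe the feature at a finite distance.
    Observed cells are never altered.
    """
    if table.feature_names != params.reference_table.feature_names:
        raise SchemaError("table schema differs from the imputer's reference table")
    mask = table.X.isna().to_numpy()
    if not mask.any():
        return table.copy()

    X = table.features()
    ref = params.reference_table.features()
    global_mean = np.nanmean(ref, axis=0)

    all_missing = np.isnan(X).all(axis=1)
    if all_missing.any():
        raise DataError(
            f"row(s) {np.flatnonzero(all_missing).tolist()} have every feature missing"
        )

    out = X.copy()
    for i in np.flatnonzero(mask.any(axis=1)):
        dist = _nan_distances(X[i], ref)
        for j in np.flatnonzero(mask[i]):
            donor = np.isfinite(dist) & ~np.isnan(ref[:, j])
            donor_idx = np.flatnonzero(donor)
            if donor_idx.size < params.k:
                logger.warning(
                    "feature %r row %d: only %d donors for k=%d; using global mean",
                    table.feature_names[j], i, donor_idx.size, params.k,
                )
                out[i, j] = global_mean[j]
                continue
            nearest = donor_idx[np.argsort(dist[donor_idx], kind="stable")[: params.k]]
            out[i, j] = ref[nearest, j].mean()

    return FeatureTable(
        pd.DataFrame(out, columns=table.feature_names),
        None if table.y is None else table.y.copy(),
    )


# ---------------------------------------------------------------------------
# SMOTE minority oversampling
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class SmoteParams:
    """Interpolation neighbourhood size, target minority:majority ratio, seed."""

    k_neighbors: int = 5
    target_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ConfigError("k_neighbors must be a positive integer")
        if not (0.0 < self.target_ratio <= 1.0):
            raise ConfigError("target_ratio must lie in (0, 1]")


def smote_oversample(table: FeatureTable, params: SmoteParams) -> FeatureTable:
    """Append interpolated minority rows until each class reaches
    target_ratio x majority count.

    Each synthetic row is x + g (x_nn - x) for a random minority row x, one of
    its k nearest same-class neighbours x_nn and g ~ U[0, 1]. Original rows
    are untouched; synthetics are appended after them, class by class in label
    order; fully reproducible from the seed.
    """
    if table.y is None:
        raise DataError("SMOTE requires a labelled table")
    if table.n_missing() > 0:
        raise DataError("SMOTE requires a complete table; impute first")

    y = table.labels()
    classes, counts = np.unique(y, return_counts=True)
    majority = counts.max()
    target = int(np.ceil(params.target_ratio * majority))

    rng = np.random.default_rng(params.seed)
    X = table.features()
    synth_X, synth_y = [], []
    for cls, count in zip(classes, counts):
        n_new = target - count
        if n_new <= 0:
            continue
        if count < 2:
            raise DataError(f"class {cls!r} has {count} row(s); SMOTE needs >= 2")
        if params.k_neighbors >= count:
            raise ConfigError(
                f"k_neighbors={params.k_neighbors} must be < minority count {count}"
            )
        Xc = X[y == cls]
        nn = NearestNeighbors(n_neighbors=params.k_neighbors + 1).fit(Xc)
        neigh = nn.kneighbors(Xc, return_distance=False)[:, 1:]  # drop self
        base = rng.integers(0, len(Xc), size=n_new)
        pick = rng.integers(0, params.k_neighbors, size=n_new)
        g = rng.random(n_new)
        anchors = Xc[base]
        partners = Xc[neigh[base, pick]]
        synth_X.append(anchors + g[:, None] * (partners - anchors))
        synth_y.append(np.full(n_new, cls, dtype=y.dtype))

    if not synth_X:
        return table.copy()
    X_out = np.vstack([X, *synth_X])
    y_out = np.concatenate([y, *synth_y])
    return FeatureTable(pd.DataFrame(X_out, columns=table.feature_names),
                        pd.Series(y_out))


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class PreprocessConfig:
    impute_k: int = 5
    smote: bool = True
    smote_k: int = 5
    target_ratio: float = 1.0
    seed: int = 0


def preprocess_pipeline(
    train: FeatureTable,
    test: FeatureTable | None,
    config: PreprocessConfig = PreprocessConfig(),
) -> tuple[FeatureTable, FeatureTable | None, ScalerParams]:
    """Impute -> standardize -> SMOTE(train only), leakage-safe.

    The imputer and scaler are fitted on the training rows only and applied
    unchanged to the test rows; no test statistic ever reaches a fitted
    parameter, and SMOTE never touches the test set.
    """
    if test is not None and test.feature_names != train.feature_names:
        raise SchemaError("train and test tables must share a feature schema")

    imputer = fit_imputer(train, k=min(config.impute_k, train.n_samples))
    train_c = knn_impute(train, imputer)
    test_c = None if test is None else knn_impute(test, imputer)

    scaler = zscore_fit(train_c)
    train_z = zscore_transform(train_c, scaler)
    test_z = None if test_c is None else zscore_transform(test_c, scaler)

    if config.smote and train_z.y is not None:
        # clamp the neighbourhood to what the smallest class can support
        min_count = int(np.unique(train_z.labels(), return_counts=True)[1].min())
        k = min(config.smote_k, max(min_count - 1, 1))
        train_z = smote_oversample(
            train_z,
            SmoteParams(k_neighbors=k,
                        target_ratio=config.target_ratio,
                        seed=config.seed),
        )
    return train_z, test_z, scaler
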