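"""Synthetic tabular classification data with EHR-like pathologies.

Real clinical extracts (readmission registries, heart-failure EHR pulls) are
class-imbalanced, carry missing cells, and are noisy. This module generates
class-conditional Gaussian blobs with exactly those pathologies so the whole
pipeline is testable offline: a deterministic minority allocation, MCAR
missingness at a configurable cell rate, and additive feature noise. It also
provides a linearly separable two-class construction used as an end-to-end
oracle (any consistent learner must reach 100% training accuracy on it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .table import FeatureTable


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic draw.

    minority_fraction allocates round(minority_fraction * n_samples) rows to the
    minority class deterministically; missing cells are MCAR over feature cells
    only (never the label); class_sep is the distance between adjacent class
    centroids and noise_sd adds isotropic jitter on top of the unit
    within-class spread, both in feature units.
    """

    n_samples: int
    n_features: int
    n_classes: int = 2
    minority_fraction: float = 0.2
    missing_rate: float = 0.0
    noise_sd: float = 0.0
    class_sep: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("n_samples must be a positive integer")
        if self.n_features < 1:
            raise ConfigError("n_features must be a positive integer")
        if self.n_classes < 2:
            raise ConfigError("n_classes must be >= 2")
        if not (0.0 < self.minority_fraction <= 0.5):
            raise ConfigError("minority_fraction must lie in (0, 0.5]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        if self.class_sep < 0:
            raise ConfigError("class_sep must be nonnegative")


def class_counts(spec: SynthSpec) -> np.ndarray:
    """Deterministic per-class row counts; the last class is the minority."""
    minority = int(round(spec.minority_fraction * spec.n_samples))
    minority = max(minority, 1)
    rest = spec.n_samples - minority
    base, extra = divmod(rest, spec.n_classes - 1)
    counts = np.full(spec.n_classes, base, dtype=int)
    counts[:extra] += 1
    counts[-1] = minority
    return counts


def generate_table(spec: SynthSpec) -> FeatureTable:
    """Draw one table per ``spec``; bit-reproducible from ``spec.seed``.

    Features for class c are N(mu_c, I) + N(0, noise_sd^2) with centroids
    spaced class_sep apart along the first feature axis. Missing cells are
    inserted completely at random at missing_rate, never in the label column.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    counts = class_counts(spec)

    blocks, labels = [], []
    for c, n_c in enumerate(counts):
        mu = np.zeros(spec.n_features)
        mu[0] = c * spec.class_sep
        x = mu + rng.standard_normal((n_c, spec.n_features))
        if spec.noise_sd > 0:
            x = x + rng.normal(0.0, spec.noise_sd, size=x.shape)
        blocks.append(x)
        labels.append(np.full(n_c, c, dtype=int))
    X = np.vstack(blocks)
    y = np.concatenate(labels)

    order = rng.permutation(spec.n_samples)
    X, y = X[order], y[order]

    if spec.missing_rate > 0:
        mask = rng.random(X.shape) < spec.missing_rate
        X = X.copy()
        X[mask] = np.nan

    cols = [f"f{j}" for j in range(spec.n_features)]
    return FeatureTable(pd.DataFrame(X, columns=cols), pd.Series(y))


def generate_separable(n: int, d: int, seed: int = 0) -> FeatureTable:
    """Two classes whose supports on feature f0 are disjoint with margin >= 4x spread.

    Class 0 draws f0 from U[0, 1], class 1 from U[5, 6]; remaining features are
    U[0, 1] nuisance. The gap (4 units) is four times the within-class support
    width, so a midpoint threshold on f0 classifies perfectly.
    """
    if n < 4:
        raise ConfigError("n must be >= 4 (two points per class)")
    if d < 1:
        raise ConfigError("d must be >= 1")
    rng = np.random.default_rng(seed)
    n0 = n - n // 2
    X = rng.random((n, d))
    y = np.concatenate([np.zeros(n0, dtype=int), np.ones(n // 2, dtype=int)])
    X[n0:, 0] += 5.0
    order = rng.permutation(n)
    cols = [f"f{j}" for j in range(d)]
    return FeatureTable(pd.DataFrame(X[order], columns=cols), pd.Series(y[order]))
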