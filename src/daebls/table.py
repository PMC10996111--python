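"""Tabular container: an n x d float feature matrix with names, missing mask and labels.

Missing cells are represented as NaN in the feature frame; the label column,
when present, never contains missing values. CSV round-trip writes missing
cells as empty fields and names the label column ``label``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError

LABEL_COLUMN = "label"


@dataclass
class FeatureTable:
    """Feature matrix (pandas DataFrame, float, NaN = missing) plus optional labels."""

    X: pd.DataFrame
    y: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.X.shape[1] == 0 or self.X.shape[0] == 0:
            raise DataError("feature table must have at least one row and one column")
        self.X = self.X.astype(float)
        if self.y is not None:
            self.y = pd.Series(np.asarray(self.y), name=LABEL_COLUMN)
            if len(self.y) != len(self.X):
                raise SchemaError(
                    f"label vector length {len(self.y)} != row count {len(self.X)}"
                )
            if self.y.isna().any():
                raise DataError("label column must not contain missing values")
        self.X.reset_index(drop=True, inplace=True)
        if self.y is not None:
            self.y.reset_index(drop=True, inplace=True)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def missing_mask(self) -> pd.DataFrame:
        return self.X.isna()

    def n_missing(self) -> int:
        return int(self.X.isna().to_numpy().sum())

    def features(self) -> np.ndarray:
        """Feature matrix as a float ndarray (NaN where missing)."""
        return self.X.to_numpy(dtype=float)

    def labels(self) -> np.ndarray:
        if self.y is None:
            raise DataError("table carries no label column")
        return self.y.to_numpy()

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.X.copy(), None if self.y is None else self.y.copy())

    def select_rows(self, idx) -> "FeatureTable":
        return FeatureTable(
            self.X.iloc[idx].reset_index(drop=True),
            None if self.y is None else self.y.iloc[idx].reset_index(drop=True),
        )

    # -- CSV round trip ----------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        frame = self.X.copy()
        if self.y is not None:
            frame[LABEL_COLUMN] = self.y.to_numpy()
        frame.to_csv(path, index=False, na_rep="")

    @classmethod
    def from_csv(cls, path: str | Path, label_column: str = LABEL_COLUMN) -> "FeatureTable":
        from .io import read_table  # avoid import cycle

        return read_table(path, label_column=label_column)
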