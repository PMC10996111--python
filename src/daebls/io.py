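"""CSV table reading and model (de)serialization.

Tables are plain CSV with a header row, a ``label`` column and empty fields
for missing cells. Models are stored as a single ``.npz`` archive: every
array of the fitted system (scaler, DAE encoders, enhancement groups, output
weights, cached A / A+ / T^n / Y needed for later increments) plus one
JSON-encoded metadata entry with a format-version field.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bls import BLSConfig, BLSModel, EnhancementGroup
from .dae import CorruptionSpec, DAEConfig, DAEModel
from .errors import DataError, SchemaError
from .preprocessing import ScalerParams
from .table import LABEL_COLUMN, FeatureTable

MODEL_FORMAT_VERSION = 1


def read_table(path: str | Path, label_column: str = LABEL_COLUMN) -> FeatureTable:
    """Parse a CSV into a FeatureTable; empty cells become the missing mask."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    frame = pd.read_csv(path)
    if frame.shape[0] == 0:
        raise DataError(f"{path}: no data rows below the header")
    has_label = label_column in frame.columns
    y = None
    if has_label:
        y = frame[label_column]
        frame = frame.drop(columns=[label_column])
    if frame.shape[1] == 0:
        raise SchemaError(f"{path}: no feature columns")
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(
                f"{path}: non-numeric value {frame[col].iloc[row]!r} "
                f"at row {row}, column {col!r}"
            )
        frame[col] = coerced
    return FeatureTable(frame, y)


def require_label(table: FeatureTable, path) -> None:
    if table.y is None:
        raise SchemaError(f"{path}: label column {LABEL_COLUMN!r} not found")


# ---------------------------------------------------------------------------
# model files
# ---------------------------------------------------------------------------
def save_model(model: BLSModel, path: str | Path, scaler: ScalerParams | None = None) -> None:
    arrays: dict[str, np.ndarray] = {
        "W": model.W, "A": model.A, "A_pinv": model.A_pinv,
        "Tn_cache": model.Tn_cache, "Y_cache": model.Y_cache,
        "classes": model.classes,
    }
    meta: dict = {
        "format_version": MODEL_FORMAT_VERSION,
        "ridge_lambda": model.ridge_lambda,
        "feature_names": model.feature_names,
        "n_mapping": len(model.mapping),
        "n_groups": len(model.groups),
        "config": None,
        "dae": [],
        "groups": [],
        "has_scaler": scaler is not None,
    }
    if model.config is not None:
        cfg = model.config
        meta["config"] = {
            "n_mapping_groups": cfg.n_mapping_groups,
            "mapping_hidden": cfg.mapping_hidden,
            "enhancement_groups": list(cfg.enhancement_groups),
            "enhancement_activation": cfg.enhancement_activation,
            "ridge_lambda": cfg.ridge_lambda,
            "seed": cfg.seed,
            "dae": vars(cfg.dae).copy(),
        }
    for i, m in enumerate(model.mapping):
        arrays[f"dae{i}_We"] = m.encoder_weights
        arrays[f"dae{i}_be"] = m.encoder_bias
        arrays[f"dae{i}_Wd"] = m.decoder_weights
        arrays[f"dae{i}_bd"] = m.decoder_bias
        meta["dae"].append({
            "activation": m.activation,
            "corruption": vars(m.corruption).copy(),
            "training_log": [float(v) for v in m.training_log],
        })
    for i, g in enumerate(model.groups):
        arrays[f"grp{i}_W"] = np.asarray(g.weights)
        arrays[f"grp{i}_b"] = np.asarray(g.bias)
        meta["groups"].append({"activation": g.activation, "scale": g.scale})
    if scaler is not None:
        arrays["scaler_mu"] = scaler.mu
        arrays["scaler_sigma"] = scaler.sigma
        meta["scaler_features"] = scaler.feature_names
    arrays["meta_json"] = np.array(json.dumps(meta))
    with open(path, "wb") as fh:  # write to the exact path, no .npz suffixing
        np.savez(fh, **arrays)


def load_model(path: str | Path) -> tuple[BLSModel, ScalerParams | None]:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such model file: {path}")
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta_json"]))
        if meta.get("format_version") != MODEL_FORMAT_VERSION:
            raise DataError(
                f"{path}: unsupported model format version {meta.get('format_version')}"
            )
        mapping = [
            DAEModel(
                encoder_weights=z[f"dae{i}_We"], encoder_bias=z[f"dae{i}_be"],
                decoder_weights=z[f"dae{i}_Wd"], decoder_bias=z[f"dae{i}_bd"],
                activation=d["activation"],
                corruption=CorruptionSpec(**d["corruption"]),
                training_log=d["training_log"],
            )
            for i, d in enumerate(meta["dae"])
        ]
        groups = [
            EnhancementGroup(z[f"grp{i}_W"], z[f"grp{i}_b"], g["activation"],
                             scale=float(g.get("scale", 1.0)))
            for i, g in enumerate(meta["groups"])
        ]
        config = None
        if meta["config"] is not None:
            c = meta["config"]
            config = BLSConfig(
                n_mapping_groups=c["n_mapping_groups"],
                mapping_hidden=c["mapping_hidden"],
                enhancement_groups=tuple(c["enhancement_groups"]),
                enhancement_activation=c["enhancement_activation"],
                ridge_lambda=c["ridge_lambda"],
                dae=DAEConfig(**c["dae"]),
                seed=c["seed"],
            )
        model = BLSModel(
            mapping=mapping, groups=groups,
            ridge_lambda=float(meta["ridge_lambda"]),
            classes=z["classes"], W=z["W"], A=z["A"], A_pinv=z["A_pinv"],
            Tn_cache=z["Tn_cache"], Y_cache=z["Y_cache"],
            config=config, feature_names=meta["feature_names"],
        )
        scaler = None
        if meta.get("has_scaler"):
            scaler = ScalerParams(z["scaler_mu"], z["scaler_sigma"],
                                  meta["scaler_features"])
    return model, scaler


def save_scaler_text(scaler: ScalerParams, path: str | Path) -> None:
    """Human-readable key-value scaler file (feature, mu, sigma per line)."""
    with open(path, "w") as fh:
        fh.write("feature\tmu\tsigma\n")
        for name, mu, sigma in zip(scaler.feature_names, scaler.mu, scaler.sigma):
            fh.write(f"{name}\t{mu!r}\t{sigma!r}\n")


def load_scaler_text(path: str | Path) -> ScalerParams:
    frame = pd.read_csv(path, sep="\t")
    return ScalerParams(
        frame["mu"].to_numpy(float), frame["sigma"].to_numpy(float),
        [str(n) for n in frame["feature"]],
    )
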