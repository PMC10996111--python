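"""End-to-end experiment harness: split -> preprocess -> fit -> evaluate.

Mirrors the usual train/test protocol for tabular disease-prediction
benchmarks: a stratified 80/20 split (the minority class stays represented in
both halves), leakage-safe preprocessing (imputer and scaler fitted on the
training rows only; SMOTE applied to the training rows only), a DAE-BLS fit,
and an evaluation report with accuracies, per-class confusion counts and
stage timings. Everything is reproducible from the config's global seed;
timings are reported but never part of any contract.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from . import __version__
from .bls import fit, predict
from .config import RunConfig, derive_seed
from .errors import DataError
from .io import read_table, require_label
from .metrics import accuracy, confusion_counts, per_class_recall
from .preprocessing import preprocess_pipeline
from .synthetic import generate_table
from .table import FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class EvalReport:
    train_accuracy: float
    test_accuracy: float
    confusion_train: dict
    confusion_test: dict
    recall_test: dict
    timings_s: dict
    config: dict
    version: str = __version__

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def stratified_split(
    table: FeatureTable, test_fraction: float, seed: int
) -> tuple[FeatureTable, FeatureTable]:
    """Stratified row split preserving class proportions in both halves."""
    if table.y is None:
        raise DataError("stratified split needs labels")
    idx = np.arange(table.n_samples)
    tr, te = train_test_split(
        idx, test_size=test_fraction, random_state=seed % 2**31,
        stratify=table.labels(),
    )
    return table.select_rows(np.sort(tr)), table.select_rows(np.sort(te))


def load_or_generate(config: RunConfig) -> FeatureTable:
    if config.data_path is not None:
        table = read_table(config.data_path)
        require_label(table, config.data_path)
        return table
    return generate_table(config.synth)


def run_experiment(config: RunConfig) -> EvalReport:
    """Run one full experiment; writes the JSON report if the config asks."""
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    try:
        table = load_or_generate(config)
    except Exception as exc:
        raise type(exc)(f"[stage: load] {exc}") from exc
    timings["load"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    train, test = stratified_split(
        table, config.test_fraction, derive_seed(config.seed, "split")
    )
    pp_cfg = dataclasses.replace(
        config.preprocess, seed=derive_seed(config.seed, "smote")
    )
    train_p, test_p, _scaler = preprocess_pipeline(train, test, pp_cfg)
    timings["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    bls_cfg = dataclasses.replace(config.bls, seed=derive_seed(config.seed, "bls"))
    model = fit(train_p, bls_cfg)
    timings["fit"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    pred_train = predict(model, train_p)
    pred_test = predict(model, test_p)
    timings["predict"] = time.perf_counter() - t0

    y_train, y_test = train_p.labels(), test_p.labels()
    report = EvalReport(
        train_accuracy=accuracy(y_train, pred_train),
        test_accuracy=accuracy(y_test, pred_test),
        confusion_train=confusion_counts(y_train, pred_train, model.classes),
        confusion_test=confusion_counts(y_test, pred_test, model.classes),
        recall_test=per_class_recall(y_test, pred_test),
        timings_s=timings,
        config=config.to_dict(),
    )
    if config.report_path:
        report.to_json(config.report_path)
    logger.info("train acc %.2f%%, test acc %.2f%%",
                report.train_accuracy, report.test_accuracy)
    return report
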