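"""Run configuration: one YAML file drives a full experiment.

All stage seeds are derived deterministically from the single global seed, so
one integer reproduces the whole run bit-for-bit (synthesis, split,
preprocessing, DAE training, enhancement draws).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .bls import BLSConfig
from .dae import DAEConfig
from .errors import ConfigError
from .preprocessing import PreprocessConfig
from .synthetic import SynthSpec


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    key = tuple(ord(c) for c in stage)
    ss = np.random.SeedSequence(global_seed, spawn_key=key)
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """Everything a full experiment needs; round-trips through YAML losslessly."""

    seed: int = 0
    data_path: str | None = None  # CSV with a label column; None -> synthesize
    synth: SynthSpec | None = None
    test_fraction: float = 0.2
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    bls: BLSConfig = field(default_factory=BLSConfig)
    report_path: str | None = None
    log_path: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.test_fraction < 1.0):
            raise ConfigError("test_fraction must lie in (0, 1)")
        if self.data_path is None and self.synth is None:
            self.synth = SynthSpec(
                n_samples=2000, n_features=20, n_classes=2,
                minority_fraction=0.3, missing_rate=0.05, noise_sd=0.5,
                class_sep=4.0, seed=derive_seed(self.seed, "synth"),
            )

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["bls"]["enhancement_groups"] = list(self.bls.enhancement_groups)
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("synth") is not None:
            d["synth"] = SynthSpec(**d["synth"])
        if d.get("preprocess") is not None:
            d["preprocess"] = PreprocessConfig(**d["preprocess"])
        if d.get("bls") is not None:
            b = dict(d["bls"])
            if b.get("dae") is not None:
                b["dae"] = DAEConfig(**b["dae"])
            if b.get("enhancement_groups") is not None:
                b["enhancement_groups"] = tuple(b["enhancement_groups"])
            d["bls"] = BLSConfig(**b)
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(f"invalid config: {exc}") from None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"no such config file: {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
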