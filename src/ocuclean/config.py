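"""Structured, validated pipeline configuration.

A nested dataclass tree mirrors the processing stages; ``from_dict`` /
``from_yaml`` reject unknown keys and every range is validated before any
computation starts.  ``config_hash`` gives a stable digest of the full
configuration for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


def _from_mapping(cls, mapping: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name not in mapping:
            continue
        value = mapping[f.name]
        if hasattr(f.type, "__dataclass_fields__") or (
            isinstance(f.default_factory, type)
            and hasattr(f.default_factory, "__dataclass_fields__")
        ):
            sub_cls = f.default_factory
            value = _from_mapping(sub_cls, value)
        kwargs[f.name] = value
    return cls(**kwargs)


@dataclass
class DataConfig:
    n_channels: int = 25
    n_eog: int = 3
    n_epochs: int = 288
    fs: float = 250.0
    duration: float = 6.0
    snr: float = 1.0
    amplitude_ratio: float = 50.0
    artifact_fraction: float = 0.5
    blink_rate: float = 0.5

    def validate(self) -> None:
        if self.n_channels < 1 or self.n_epochs < 1:
            raise ConfigError("n_channels and n_epochs must be positive")
        if not 0 < self.artifact_fraction <= 1:
            raise ConfigError("artifact_fraction must lie in (0, 1]")
        if self.snr <= 0:
            raise ConfigError("snr must be positive")


@dataclass
class DecompConfig:
    wavelet: str = "db4"
    pisarenko_order: int = 8
    pisarenko_grid: int = 256

    def validate(self) -> None:
        if self.pisarenko_order < 3:
            raise ConfigError("pisarenko_order must be >= 3")
        if self.pisarenko_grid < 8:
            raise ConfigError("pisarenko_grid must be >= 8")


@dataclass
class FeatureConfig:
    n_components: int = 83

    def validate(self) -> None:
        if self.n_components < 1:
            raise ConfigError("n_components must be >= 1")


@dataclass
class DsefoConfig:
    pop: int = 6
    iters: int = 10
    beta: float = 0.5
    reinit_prob: float = 0.1
    variant: str = "ds-efo"

    def validate(self) -> None:
        if self.pop < 2:
            raise ConfigError("pop must be >= 2")
        if self.variant.lower().replace("_", "-") not in {"efo", "ds-efo"}:
            raise ConfigError(f"unknown variant {self.variant!r}")


@dataclass
class DetectorConfig:
    epochs: int = 15
    learning_rate: float = 0.3
    batch_size: int = 16
    tune: bool = False

    def validate(self) -> None:
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if not self.learning_rate > 0:
            raise ConfigError("learning_rate must be positive")


@dataclass
class DenoiserConfig:
    epochs: int = 15
    learning_rate: float = 0.3
    batch_size: int = 16
    tune: bool = False
    component: str = "leftover"  # which EMCD part the denoiser restores
    max_levels: int = 2
    decimation: int = 8  # the trend is band-limited; denoise it decimated
    max_train_signals: int = 512
    passthrough: bool = False  # identity denoiser (conservation baseline)

    def validate(self) -> None:
        if self.component not in {"leftover", "modes"}:
            raise ConfigError("component must be 'leftover' or 'modes'")
        if self.max_levels < 1:
            raise ConfigError("max_levels must be >= 1")
        if self.decimation < 1:
            raise ConfigError("decimation must be >= 1")


@dataclass
class SplitConfig:
    train: float = 0.6
    val: float = 0.1
    test: float = 0.3

    def validate(self) -> None:
        total = self.train + self.val + self.test
        if abs(total - 1.0) > 1e-9:
            raise ConfigError("split fractions must sum to 1")
        if min(self.train, self.val, self.test) < 0:
            raise ConfigError("split fractions must be nonnegative")


@dataclass
class PipelineConfig:
    seed: int = 0
    data: DataConfig = field(default_factory=DataConfig)
    decomp: DecompConfig = field(default_factory=DecompConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    dsefo: DsefoConfig = field(default_factory=DsefoConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    denoiser: DenoiserConfig = field(default_factory=DenoiserConfig)
    split: SplitConfig = field(default_factory=SplitConfig)

    def __post_init__(self) -> None:
        for section in (
            self.data,
            self.decomp,
            self.features,
            self.dsefo,
            self.detector,
            self.denoiser,
            self.split,
        ):
            section.validate()

    @classmethod
    def from_dict(cls, mapping: dict) -> "PipelineConfig":
        return _from_mapping(cls, mapping)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            mapping = yaml.safe_load(fh) or {}
        return cls.from_dict(mapping)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
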