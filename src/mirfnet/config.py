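"""Resolved model configuration: every architectural hyperparameter with its
default, plus YAML round-tripping for the CLI."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .encoders import CTGEncoderConfig, ImageEncoderConfig, MetadataEncoderConfig
from .gadf import GADFConfig

__all__ = ["FusionConfig", "LossConfig", "ModelConfig"]

MODALITIES = ("signal", "image", "metadata")
STRATEGIES = ("transformer", "concat", "add", "mlp")


@dataclass
class FusionConfig:
    d_common: int = 128
    n_layers: int = 2
    n_heads: int = 4
    ffn_width: int = 256
    dropout: float = 0.1
    strategy: str = "transformer"
    modality_mask: tuple = MODALITIES

    def __post_init__(self):
        requested = tuple(self.modality_mask)
        unknown = set(requested) - set(MODALITIES)
        if unknown:
            raise ValueError(f"unknown modalities in mask: {sorted(unknown)}")
        self.modality_mask = tuple(m for m in MODALITIES if m in requested)
        if not self.modality_mask:
            raise ValueError("modality_mask must keep at least one modality")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown fusion strategy {self.strategy!r}")
        if self.d_common % self.n_heads:
            raise ValueError("d_common must be divisible by n_heads")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")


@dataclass
class LossConfig:
    smoothing: float = 0.1
    recon_weight: float = 0.5
    n_classes: int = 2

    def __post_init__(self):
        if not 0.0 <= self.smoothing < 1.0:
            raise ValueError("smoothing must be in [0, 1)")
        if self.recon_weight < 0:
            raise ValueError("recon_weight must be >= 0")


@dataclass
class ModelConfig:
    segment_length: int = 7200
    signals: tuple = ("fhr", "uc")
    ctg: CTGEncoderConfig = field(default_factory=CTGEncoderConfig)
    image: ImageEncoderConfig = field(default_factory=ImageEncoderConfig)
    metadata: MetadataEncoderConfig = field(default_factory=MetadataEncoderConfig)
    gadf: GADFConfig = field(default_factory=GADFConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self):
        self.signals = tuple(self.signals)
        if not set(self.signals) <= {"fhr", "uc"} or "fhr" not in self.signals:
            raise ValueError("signals must be ('fhr',) or ('fhr','uc')")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        kwargs = dict(d)
        for f in fields(cls):
            if f.name in kwargs and isinstance(kwargs[f.name], dict):
                sub = f.default_factory()  # type: ignore[misc]
                kwargs[f.name] = type(sub)(**kwargs[f.name])
        return cls(**kwargs)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
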