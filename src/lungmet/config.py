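"""One YAML document configuring every pipeline stage, validated on load.

Top-level keys: ``spacing_mm``, ``seed``, and the per-stage blocks
``network``, ``loss``, ``train``, ``postprocess``, ``augment``. Unknown
keys anywhere are rejected, so typos fail loudly instead of silently
falling back to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .augment import ElasticParams
from .core_io import DEFAULT_SPACING_MM
from .loss import LossConfig
from .network import NetworkSpec
from .postprocess import PostprocessParams
from .train import TrainConfig

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised for unknown keys or invalid values in a config document."""


def _build(cls, block: dict, name: str):
    if block is None:
        block = {}
    if not isinstance(block, dict):
        raise ConfigError(f"config block {name!r} must be a mapping")
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {name!r}: {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in block.items()
    }
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {name!r} block: {exc}") from exc


@dataclass(frozen=True)
class PipelineConfig:
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM
    seed: int = 0
    network: NetworkSpec = field(default_factory=NetworkSpec)
    loss: LossConfig = field(default_factory=LossConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    postprocess: PostprocessParams = field(default_factory=PostprocessParams)
    augment: ElasticParams = field(default_factory=ElasticParams)

    def __post_init__(self):
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ConfigError(f"spacing_mm must be three positive values, got {self.spacing_mm}")

    @staticmethod
    def from_dict(doc: dict) -> "PipelineConfig":
        doc = dict(doc or {})
        blocks = {
            "network": NetworkSpec, "loss": LossConfig, "train": TrainConfig,
            "postprocess": PostprocessParams, "augment": ElasticParams,
        }
        allowed = set(blocks) | {"spacing_mm", "seed"}
        unknown = set(doc) - allowed
        if unknown:
            raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
        kwargs = {}
        if "spacing_mm" in doc:
            kwargs["spacing_mm"] = tuple(doc["spacing_mm"])
        if "seed" in doc:
            kwargs["seed"] = int(doc["seed"])
        for name, cls in blocks.items():
            kwargs[name] = _build(cls, doc.get(name), name)
        return PipelineConfig(**kwargs)

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(Path(path)) as fh:
            doc = yaml.safe_load(fh)
        if doc is None:
            doc = {}
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: config document must be a mapping")
        return PipelineConfig.from_dict(doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        """Stable hash of the full configuration, for provenance records."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
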