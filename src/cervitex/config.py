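"""Pipeline configuration.

One config object pins every silent parameter of the pipeline (enhancement
window, transform wavelet, feature subset, network training, morphology) so a
run is reproducible from its config + seed alone.  Configs round-trip
losslessly through YAML, and a short hash of the canonical form is stamped
into every output artifact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import yaml

from .classify import TrainConfig
from .segmentation import StructuringElement
from .texture import FeatureConfig

__all__ = ["EnhancementConfig", "ClassifierConfig", "SegmentationConfig", "PipelineConfig"]


@dataclass(frozen=True)
class EnhancementConfig:
    window: int = 3
    fusion: str = "max"
    levels: int = 256


@dataclass(frozen=True)
class ClassifierConfig:
    train: TrainConfig = field(default_factory=TrainConfig)
    k: int = 2


@dataclass(frozen=True)
class SegmentationConfig:
    se_shape: str = "disk"
    se_size: int = 3
    min_area: int = 25
    method: str = "otsu"
    #: morphology order; closing first solidifies texture-riddled masks
    operation: str = "close_open"
    #: binarization source: the raw grayscale image ("gray") or the
    #: AHE-enhanced image ("enhanced").  Default "gray": windowed equalization
    #: is rank-based and removes the global brightness separation a global
    #: threshold needs (see docs/methods.md).
    source: str = "gray"
    #: segment every image rather than only classifier-abnormal calls
    force: bool = False

    def element(self) -> StructuringElement:
        return StructuringElement(self.se_shape, self.se_size)


@dataclass(frozen=True)
class PipelineConfig:
    enhancement: EnhancementConfig = field(default_factory=EnhancementConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    seed: int = 0
    log_level: str = "INFO"

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["features"]["blocks"] = list(self.features.blocks)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        feats = dict(d.get("features", {}))
        if "blocks" in feats:
            feats["blocks"] = tuple(feats["blocks"])
        clf = dict(d.get("classifier", {}))
        if "train" in clf:
            clf["train"] = TrainConfig(**clf["train"])
        return cls(
            enhancement=EnhancementConfig(**d.get("enhancement", {})),
            features=FeatureConfig(**feats),
            classifier=ClassifierConfig(**clf),
            segmentation=SegmentationConfig(**d.get("segmentation", {})),
            seed=d.get("seed", 0),
            log_level=d.get("log_level", "INFO"),
        )

    def to_yaml(self, path: str | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def with_overrides(self, **sections) -> "PipelineConfig":
        """Functional update of whole sections (enhancement=..., seed=..., ...)."""
        current = {
            "enhancement": self.enhancement,
            "features": self.features,
            "classifier": self.classifier,
            "segmentation": self.segmentation,
            "seed": self.seed,
            "log_level": self.log_level,
        }
        current.update(sections)
        return PipelineConfig(**current)
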