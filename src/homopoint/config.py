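"""Pipeline configuration: model, landmark, TPS, preprocessing and training
parameters in one serializable record (YAML or JSON)."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .model import ModelConfig
from .training import AugmentationParams

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclasses.dataclass
class PipelineConfig:
    # model
    image_size: int = 512
    patch_size: int = 16
    embed_dim: int = 128
    n_blocks: int = 6
    n_heads: int = 4
    L: int = 75
    ffn_expansion: int = 4
    use_layernorm: bool = True
    similarity_temperature: float = 1.0
    # landmark selection
    contrast_threshold: float = 0.04
    edge_fraction: float = 0.19
    min_dist: float = 30.0
    # transform resolver
    tps_regularization: float = 0.0
    # preprocessing
    pad: int = 50
    # training
    epochs: int = 128
    tps_max_dev: float = 16.0
    rotation_deg: float = 20.0
    same_modality_fraction: float = 0.5
    lr: float = 1e-4
    batch_size: int = 4

    def model_config(self) -> ModelConfig:
        return ModelConfig(
            image_size=self.image_size,
            patch_size=self.patch_size,
            embed_dim=self.embed_dim,
            n_blocks=self.n_blocks,
            n_heads=self.n_heads,
            L=self.L,
            ffn_expansion=self.ffn_expansion,
            use_layernorm=self.use_layernorm,
            similarity_temperature=self.similarity_temperature,
        )

    def augmentation_params(self) -> AugmentationParams:
        return AugmentationParams(tps_max_dev=self.tps_max_dev, rotation_deg=self.rotation_deg)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML/JSON config; an empty file yields all defaults; unknown
    keys are rejected by name."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text) if text.strip() else {}
    else:
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    return PipelineConfig(**data)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg.to_dict(), indent=2))
    else:
        path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
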