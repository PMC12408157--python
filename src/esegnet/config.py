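"""Model and training configuration (YAML-serializable dataclasses)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import yaml

from .losses import default_loss_weights

__all__ = ["ModelConfig", "TrainConfig", "build_model", "load_yaml",
           "dump_yaml", "desk_train_config", "paper_train_config"]


@dataclass
class ModelConfig:
    dim: int = 2
    num_classes: int = 2
    in_channels: int = 1
    aggregation_width: int = 64
    stage_subset: Optional[Tuple[int, ...]] = None  # None -> dim default
    refinement: str = "mlkconv"
    encoder: str = "toy2d"
    encoder_options: dict = field(default_factory=dict)
    loss_weights: Optional[Tuple[float, float]] = None  # None -> dim default
    upconv_order: str = "conv_relu_bn"
    seed: int = 0

    def __post_init__(self):
        if self.dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.aggregation_width % 4:
            raise ValueError("aggregation_width must be divisible by 4")
        if self.stage_subset is not None:
            self.stage_subset = tuple(int(i) for i in self.stage_subset)
            if not self.stage_subset:
                raise ValueError("stage_subset must not be empty")
        if self.loss_weights is not None:
            self.loss_weights = tuple(float(w) for w in self.loss_weights)

    @property
    def resolved_loss_weights(self) -> Tuple[float, float]:
        return self.loss_weights or default_loss_weights(self.dim)


def build_model(cfg: ModelConfig):
    """Instantiate the E-model a :class:`ModelConfig` describes."""
    from .models import EModel, build_encoder
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    enc = build_encoder(cfg.encoder, rng=rng,
                        in_channels=cfg.in_channels, **cfg.encoder_options)
    return EModel(enc, cfg.num_classes,
                  aggregation_width=cfg.aggregation_width,
                  stage_subset=cfg.stage_subset,
                  refinement=cfg.refinement,
                  upconv_order=cfg.upconv_order,
                  rng=rng)


@dataclass
class TrainConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    lr: float = 1e-4
    weight_decay: float = 0.01
    epochs: int = 400
    batch_size: int = 8
    # 3D patch sampling
    patch_size: Optional[Tuple[int, ...]] = (128, 128, 64)
    patches_per_epoch: int = 250
    fg_bias: float = 0.5
    augment_flips: bool = False
    max_steps: Optional[int] = None
    stop_train_dsc: Optional[float] = None  # early stop once train DSC passes
    eval_every: int = 25
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.model, dict):
            self.model = ModelConfig(**self.model)
        if self.patch_size is not None:
            self.patch_size = tuple(int(p) for p in self.patch_size)


def paper_train_config(dim: int, **overrides) -> TrainConfig:
    """Published full-scale training settings (GPU-scale; not what the desk
    profile runs)."""
    if dim == 2:
        base = dict(lr=1e-4, epochs=400, batch_size=8, patch_size=None)
    else:
        base = dict(lr=1e-4, epochs=1000, batch_size=2,
                    patch_size=(128, 128, 64), patches_per_epoch=250)
    base["model"] = overrides.pop("model", ModelConfig(dim=dim))
    base.update(overrides)
    return TrainConfig(**base)


def desk_train_config(dim: int, **overrides) -> TrainConfig:
    """Laptop-scale profile: small toy encoder, short schedule, Adam-typical
    learning rate for tiny models, overfit-verification early stop."""
    if dim == 2:
        model = ModelConfig(dim=2, num_classes=4, aggregation_width=32,
                            encoder="toy2d",
                            encoder_options={"widths": (8, 16, 24, 32, 48)})
        base = dict(model=model, lr=1e-3, epochs=600, batch_size=4,
                    patch_size=None, max_steps=600, stop_train_dsc=0.98,
                    eval_every=20)
    else:
        model = ModelConfig(dim=3, num_classes=3, aggregation_width=16,
                            encoder="toy3d",
                            encoder_options={"widths": (8, 12, 16, 24, 32)})
        base = dict(model=model, lr=1e-3, epochs=600, batch_size=2,
                    patch_size=(32, 32, 16), patches_per_epoch=2,
                    max_steps=600, stop_train_dsc=0.92, eval_every=30)
    mo = overrides.pop("model", None)
    if mo is not None:
        base["model"] = mo
    base.update(overrides)
    return TrainConfig(**base)


def dump_yaml(cfg, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)


def load_yaml(path, kind="train"):
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if kind == "model":
        return ModelConfig(**raw)
    if kind == "train":
        return TrainConfig(**raw)
    raise ValueError(f"unknown config kind {kind!r}")
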