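"""Configuration objects and YAML (de)serialisation.

Three dataclasses mirror the tunable surface of the framework: the
model topology (:class:`ModelConfig`), the composite segmentation loss
(:class:`LossConfig`) and the two-stage schedule (:class:`TrainConfig`).
``load_config``/``save_config`` round-trip the trio through one YAML
document so an experiment is fully described by a single file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["ModelConfig", "LossConfig", "TrainConfig", "ExperimentConfig",
           "load_config", "save_config"]

INSERTION_POINTS = ("L0", "L1", "L2", "L3", "L4")


@dataclass
class ModelConfig:
    """Topology of the dual-branch model.

    ``insertion_points`` selects the backbone scales that receive an
    attention block (L0 = stem output, L1..L4 = the residual stages).
    ``placement`` is 'per_layer' (one block after each selected stage)
    or 'per_block' (one after every residual block of the selected
    stages — the dense-enhancement ablation).  ``width_multiplier``
    scales every channel count, used to shrink models for CPU-scale
    experiments.
    """

    num_classes: int = 2
    insertion_points: tuple[str, ...] = INSERTION_POINTS
    placement: str = "per_layer"
    attention_variant: str = "parallel"
    width_multiplier: float = 1.0
    input_size: int = 224
    mlp_reduction: int = 16
    include_segmentation: bool = True

    def __post_init__(self):
        self.insertion_points = tuple(self.insertion_points)
        bad = [p for p in self.insertion_points if p not in INSERTION_POINTS]
        if bad:
            raise ValueError(f"unknown insertion points {bad}; valid: {INSERTION_POINTS}")
        if self.placement not in ("per_layer", "per_block"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.attention_variant != "none" and not self.insertion_points:
            raise ValueError("insertion_points must be nonempty unless attention is off")
        if self.input_size % 32 != 0:
            raise ValueError("input_size must be divisible by 32")


@dataclass
class LossConfig:
    """alpha weights BCE against Dice in the segmentation loss;
    eps_dice is the Dice smoothing constant."""

    alpha: float = 0.5
    eps_dice: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.eps_dice <= 0:
            raise ValueError("eps_dice must be positive")


@dataclass
class TrainConfig:
    """Two-stage schedule: segmentation pre-training, then joint training."""

    lr: float = 1e-4
    batch_size: int = 32
    epochs_pretrain: int = 60
    epochs_joint: int = 140
    hflip_prob: float = 0.5
    seed: int = 0
    n_runs: int = 5
    tiny: bool = False

    @property
    def total_epochs(self) -> int:
        return self.epochs_pretrain + self.epochs_joint

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")


@dataclass
class ExperimentConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def to_dict(self) -> dict:
        d = {"model": asdict(self.model), "loss": asdict(self.loss),
             "train": asdict(self.train)}
        d["model"]["insertion_points"] = list(self.model.insertion_points)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(model=ModelConfig(**d.get("model", {})),
                   loss=LossConfig(**d.get("loss", {})),
                   train=TrainConfig(**d.get("train", {})))


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        return ExperimentConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(config: ExperimentConfig, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return path
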