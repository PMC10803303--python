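"""Classifier variants and training hyperparameters."""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["ClassifierConfig", "ClsTrainLog", "VARIANTS"]

VARIANTS = ("plain_resnet10", "mlnet", "stage1", "stage2", "stage3", "stage4")


@dataclass
class ClassifierConfig:
    variant: str = "mlnet"
    input_channels: int = 1
    base_width: int = 8
    learning_rate: float = 1e-4
    batch_size: int = 4
    patience: int = 10
    max_epochs: int = 100
    class_weight: float | None = None  # None -> neg/pos on the training split
    sam_rho: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.sam_rho < 0:
            raise ValueError("sam_rho must be >= 0")

    @property
    def injected_stages(self) -> frozenset[int]:
        """Variant algebra: mlnet injects all 4 stages, stageN injects {N},
        the plain backbone injects nothing."""
        if self.variant == "mlnet":
            return frozenset({1, 2, 3, 4})
        if self.variant.startswith("stage"):
            return frozenset({int(self.variant[-1])})
        return frozenset()

    @property
    def uses_skip(self) -> bool:
        """Only the plain backbone keeps its identity shortcuts."""
        return self.variant == "plain_resnet10"


@dataclass
class ClsTrainLog:
    epochs: list[dict] = field(default_factory=list)  # train_loss, val_loss
    checkpoint_epoch: int = -1
    stop_epoch: int = -1

    def train_losses(self) -> list[float]:
        return [e["train_loss"] for e in self.epochs]

    def val_losses(self) -> list[float]:
        return [e["val_loss"] for e in self.epochs]
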