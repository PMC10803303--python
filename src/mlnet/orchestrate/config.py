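"""Experiment configuration: one YAML document drives the whole run."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from ..classification.config import VARIANTS, ClassifierConfig
from ..phantom.types import PhantomSpec
from ..segmentation.types import UNetConfig
from .split import SplitPlan

__all__ = ["ExperimentConfig"]

_ARMS = {"dwi": 1, "dwi_t2w": 2}  # arm name -> input channels


@dataclass
class ExperimentConfig:
    n_cases: int = 60
    n_centres: int = 9
    p_emvi: float = 0.60
    p_cr: float = 0.28
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    train_centres: tuple[str, ...] = ("C1", "C2", "C3", "C4")
    internal_val_centres: tuple[str, ...] = ("C5", "C6")
    external_centres: tuple[str, ...] = ("C7", "C8", "C9")
    arms: tuple[str, ...] = ("dwi",)
    tasks: tuple[str, ...] = ("emvi", "cr")
    variants: tuple[str, ...] = VARIANTS
    seg_folds: int = 4
    seg_epochs: int = 8
    seg_lr: float = 3e-3
    seg_base_channels: int = 8
    cls_epochs: int = 20
    cls_lr: float = 1e-4
    cls_batch_size: int = 4
    cls_patience: int = 10
    cls_base_width: int = 8
    sam_rho: float = 0.05
    n_boot: int = 1000
    n_attention_cases: int = 2
    run_seg_cv: bool = True
    seed: int = 0
    phantom: dict = field(default_factory=dict)

    def __post_init__(self):
        for arm in self.arms:
            if arm not in _ARMS:
                raise ValueError(f"unknown arm {arm!r}; choose from {sorted(_ARMS)}")
        for task in self.tasks:
            if task not in ("emvi", "cr"):
                raise ValueError(f"unknown task {task!r}")
        if not self.arms or not self.tasks:
            raise ValueError("arms and tasks must be nonempty")

    # ------------------------------------------------------------ derived
    def split_plan(self) -> SplitPlan:
        return SplitPlan(self.train_centres, self.internal_val_centres,
                         self.external_centres)

    def phantom_spec(self) -> PhantomSpec:
        return PhantomSpec(grid_shape=self.grid_shape, **self.phantom)

    def arm_channels(self, arm: str) -> int:
        return _ARMS[arm]

    def unet_config(self, arm: str) -> UNetConfig:
        return UNetConfig(
            base_channels=self.seg_base_channels,
            input_channels=self.arm_channels(arm),
            seed=self.seed + 101,
        )

    def classifier_config(self, arm: str, variant: str) -> ClassifierConfig:
        return ClassifierConfig(
            variant=variant,
            input_channels=self.arm_channels(arm),
            base_width=self.cls_base_width,
            learning_rate=self.cls_lr,
            batch_size=self.cls_batch_size,
            patience=self.cls_patience,
            max_epochs=self.cls_epochs,
            sam_rho=self.sam_rho,
            seed=self.seed + 211,
        )

    # ---------------------------------------------------------------- yaml
    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("grid_shape", "train_centres", "internal_val_centres",
                    "external_centres", "arms", "tasks", "variants"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)
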