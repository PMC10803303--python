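"""Configuration and result types for the miniature segmenter."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["UNetConfig", "FeaturePyramid", "SegTrainLog", "default_ds_weights"]


def default_ds_weights(n_stages: int) -> np.ndarray:
    """Deep-supervision weights proportional to 2^(1-s), normalised."""
    w = 2.0 ** (1 - np.arange(1, n_stages + 1, dtype=np.float64))
    return w / w.sum()


@dataclass
class UNetConfig:
    n_stages: int = 4
    base_channels: int = 8
    input_channels: int = 1
    convs_per_stage: int = 2
    ds_weights: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_stages < 2:
            raise ValueError("n_stages must be >= 2")
        if self.base_channels < 2:
            raise ValueError("base_channels must be >= 2")
        if self.input_channels not in (1, 2):
            raise ValueError("input_channels must be 1 or 2")
        if self.ds_weights is None:
            self.ds_weights = tuple(default_ds_weights(self.n_stages))
        else:
            w = np.asarray(self.ds_weights, dtype=np.float64)
            if w.size != self.n_stages or (w < 0).any():
                raise ValueError("ds_weights must be n_stages nonnegative reals")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("ds_weights must sum to 1")
            self.ds_weights = tuple(float(x) for x in w)

    @property
    def stage_channels(self) -> tuple[int, ...]:
        return tuple(self.base_channels * 2 ** s for s in range(self.n_stages))


@dataclass
class FeaturePyramid:
    """Decoder feature volumes, stage 1 finest; stage s is downsampled by
    2^(s-1) relative to the input grid."""

    stages: list[np.ndarray]  # each (C_s, D_s, H_s, W_s)

    def __post_init__(self):
        if not self.stages:
            raise ValueError("empty pyramid")
        for s in range(1, len(self.stages)):
            prev = np.array(self.stages[s - 1].shape[1:])
            cur = np.array(self.stages[s].shape[1:])
            if not np.all((prev + 1) // 2 == cur):
                raise ValueError(
                    f"stage {s + 1} shape {tuple(cur)} does not halve stage "
                    f"{s} shape {tuple(prev)}"
                )

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(f.shape[0] for f in self.stages)

    def stage(self, s: int) -> np.ndarray:
        """1-based stage accessor (stage 1 = finest)."""
        return self.stages[s - 1]


@dataclass
class SegTrainLog:
    epochs: list[dict] = field(default_factory=list)  # train_loss, val_dice
    checkpoint_epoch: int = -1

    def train_losses(self) -> list[float]:
        return [e["train_loss"] for e in self.epochs]

    def val_dices(self) -> list[float]:
        return [e["val_dice"] for e in self.epochs]
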