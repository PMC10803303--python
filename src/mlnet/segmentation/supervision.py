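"""Deep-supervision targets and the combined segmentation loss."""

from __future__ import annotations

import numpy as np

from ..nn import Tensor, bce_with_logits, soft_dice_loss, stack_losses, trilinear_resize

__all__ = ["downsample_targets", "deep_supervision_loss", "stage_shapes"]


def stage_shapes(shape, n_stages: int) -> list[tuple[int, int, int]]:
    """Spatial dims per stage: each stride-2 level is ceil(previous / 2)."""
    shapes = [tuple(shape)]
    for _ in range(n_stages - 1):
        shapes.append(tuple((d + 1) // 2 for d in shapes[-1]))
    return shapes


def downsample_targets(mask, n_stages: int) -> list[np.ndarray]:
    """Soft masks at scales 2^(1-s), trilinearly interpolated.

    Level 1 is the original mask (float); deeper levels are in [0, 1].
    """
    if n_stages < 1:
        raise ValueError("n_stages must be >= 1")
    data = np.asarray(getattr(mask, "data", mask), dtype=np.float32)
    targets = [data.copy()]
    for shp in stage_shapes(data.shape, n_stages)[1:]:
        targets.append(trilinear_resize(data, shp))
    return targets


def deep_supervision_loss(preds: list[Tensor], targets: list[np.ndarray], weights) -> Tensor:
    """Sum_s w_s * (soft-Dice loss + voxel BCE) at stage s."""
    if len(preds) != len(targets):
        raise ValueError("preds and targets must have one entry per stage")
    w = np.asarray(weights, dtype=np.float64)
    if w.size != len(preds) or (w < 0).any():
        raise ValueError("weights must be nonnegative, one per stage")
    losses = []
    for p, t in zip(preds, targets):
        t = np.asarray(t, dtype=np.float32)
        if t.ndim == p.ndim - 2:  # add batch/channel axes
            t = t[None, None]
        if t.shape != p.shape:
            raise ValueError(f"stage shape mismatch: pred {p.shape}, target {t.shape}")
        losses.append(soft_dice_loss(p, t) + bce_with_logits(p, t))
    return stack_losses(losses, w)
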