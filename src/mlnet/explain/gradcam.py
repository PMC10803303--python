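"""Grad-CAM++ attention maps for the 3D classifiers.

3D generalisation of the gradient-weighted class-activation method: the
per-channel weight denominators sum activations over all three spatial
axes. Maps are clamped nonnegative, trilinearly upsampled to the input grid
and max-normalised into [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation

from ..nn import Tensor, trilinear_resize
from ..classification.resnet import Classifier3D

__all__ = ["AttentionMap", "gradcam_pp", "attention_overlap", "default_target_layer"]


@dataclass
class AttentionMap:
    """Nonnegative saliency on the input spatial grid, max-normalised to 1
    whenever any activation survives the clamp."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("attention map must be 3D")
        if (self.data < 0).any() or self.data.max() > 1.0 + 1e-6:
            raise ValueError("attention values must lie in [0, 1]")


def default_target_layer(model: Classifier3D) -> str:
    """Last injected block's activation; the final block for the plain net."""
    stages = model.config.injected_stages
    return f"block{max(stages)}" if stages else "block4"


def gradcam_pp(model: Classifier3D, x: np.ndarray,
               injected: dict[int, np.ndarray] | None = None,
               target_layer: str | None = None) -> AttentionMap:
    """Grad-CAM++ map for one case.

    ``x`` is the normalised input (C, D, H, W). Channel weights use the
    positive-gradient alpha weighting; a constant-output model (zero
    gradient everywhere) yields an all-zero map.
    """
    if target_layer is None:
        target_layer = default_target_layer(model)
    xt = Tensor(np.asarray(x, dtype=np.float32)[None])
    inj = None
    if injected is not None:
        inj = {s: f[None] if f.ndim == 4 else f for s, f in injected.items()}
    logit = model(xt, inj, capture=True)
    if target_layer not in model.activations:
        raise ValueError(
            f"layer {target_layer!r} not captured; available: "
            f"{sorted(model.activations)}"
        )
    act = model.activations[target_layer]
    if act.ndim != 5:
        raise ValueError("target layer has no spatial extent")
    logit.backward(np.ones_like(logit.data))
    A = act.data[0].astype(np.float64)  # (C, d, h, w)
    G = (act.grad[0] if act.grad is not None else np.zeros_like(A)).astype(np.float64)

    g2 = G**2
    g3 = G**3
    denom = 2.0 * g2 + (A * g3).sum(axis=(1, 2, 3), keepdims=True)
    alpha = np.where(np.abs(denom) > 1e-12, g2 / np.where(denom == 0, 1.0, denom), 0.0)
    weights = (alpha * np.maximum(G, 0.0)).sum(axis=(1, 2, 3))  # per channel
    cam = np.maximum((weights[:, None, None, None] * A).sum(axis=0), 0.0)

    up = trilinear_resize(cam.astype(np.float32), tuple(np.asarray(x).shape[1:]))
    up = np.maximum(up, 0.0)
    peak = up.max()
    if peak > 0:
        up = up / peak
    return AttentionMap(up)


def attention_overlap(attention: AttentionMap, mask, quantile: float = 0.9,
                      margin: int = 2) -> float:
    """Fraction of top-quantile attention voxels inside the mask dilated by
    ``margin`` voxels (the peri-tumoural band included)."""
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    m = np.asarray(getattr(mask, "data", mask)).astype(bool)
    a = attention.data
    if a.shape != m.shape:
        raise ValueError("attention map and mask grids differ")
    if not m.any():
        raise ValueError("empty mask")
    dilated = binary_dilation(m, iterations=margin) if margin > 0 else m
    thr = np.quantile(a, quantile)
    # a sparse map can push the quantile to 0; zero attention is never "top"
    top = (a >= thr) & (a > 0) if thr == 0 else a >= thr
    if not top.any():
        return 0.0
    return float((top & dilated).sum() / top.sum())
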