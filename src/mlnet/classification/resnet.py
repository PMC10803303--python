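"""3D ResNet10-family classifier with stage-wise feature injection.

Backbone: stem convolution (stride 2) + 4 residual-style blocks of 2
convolutions each + linear head = 10 weighted layers. For the injecting
variants (mlnet / stageN) the identity shortcut is removed and the stage-s
segmentation features, trilinearly resampled to the block-s input
resolution, are concatenated to that block's input. The plain backbone
keeps its shortcuts and ignores any supplied pyramid. The original image is
always an input.
"""

from __future__ import annotations

import numpy as np

from ..nn import (
    Conv3d,
    InstanceNorm3d,
    Linear,
    Module,
    Tensor,
    concat,
    global_avg_pool,
    trilinear_resize,
)
from ..segmentation.types import FeaturePyramid
from .config import ClassifierConfig

__all__ = ["ResidualBlock", "Classifier3D", "build_classifier", "prepare_injection"]


class ResidualBlock(Module):
    def __init__(self, in_ch: int, out_ch: int, stride: int, use_skip: bool, rng):
        self.in_ch, self.out_ch, self.stride, self.use_skip = in_ch, out_ch, stride, use_skip
        self.conv1 = Conv3d(in_ch, out_ch, k=3, stride=stride, rng=rng)
        self.norm1 = InstanceNorm3d(out_ch)
        self.conv2 = Conv3d(out_ch, out_ch, k=3, rng=rng)
        self.norm2 = InstanceNorm3d(out_ch)
        self.proj = None
        if use_skip and (in_ch != out_ch or stride != 1):
            self.proj = Conv3d(in_ch, out_ch, k=1, stride=stride, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.norm1(self.conv1(x)).relu()
        h = self.norm2(self.conv2(h))
        if self.use_skip:
            shortcut = self.proj(x) if self.proj is not None else x
            h = h + shortcut
        return h.relu()


class Classifier3D(Module):
    """Stem (stride 1) + 4 stride-2 residual-style blocks + linear head.

    With this stride plan the input of block s sits at exactly the stage-s
    pyramid resolution (input / 2^(s-1)), so injected features concatenate
    at native scale and block 1's strided convolution reads the finest
    stage at full resolution.
    """

    N_BLOCKS = 4
    STRIDES = (2, 2, 2, 2)

    def __init__(self, config: ClassifierConfig, pyramid_channels: dict[int, int]):
        self.config = config
        missing = config.injected_stages - set(pyramid_channels)
        if missing:
            raise ValueError(f"no channel spec for injected stages {sorted(missing)}")
        self.pyramid_channels = {
            s: pyramid_channels[s] for s in sorted(config.injected_stages)
        }
        rng = np.random.default_rng(config.seed)
        w = config.base_width
        widths = (w, 2 * w, 4 * w, 8 * w)
        self.stem = Conv3d(config.input_channels, w, k=3, stride=1, rng=rng)
        self.stem_norm = InstanceNorm3d(w)
        self.blocks = []
        in_ch = w
        for b in range(self.N_BLOCKS):
            extra = self.pyramid_channels.get(b + 1, 0)
            self.blocks.append(
                ResidualBlock(in_ch + extra, widths[b], self.STRIDES[b],
                              config.uses_skip, rng)
            )
            in_ch = widths[b]
        self.head = Linear(widths[-1], 1, rng=rng)
        self.activations: dict[str, Tensor] = {}

    def block_input_shapes(self, input_spatial) -> list[tuple[int, int, int]]:
        """Spatial resolution at the input of each block, for injection."""
        cur = tuple(input_spatial)  # stem keeps full resolution
        shapes = []
        for b in range(self.N_BLOCKS):
            shapes.append(cur)
            if self.STRIDES[b] == 2:
                cur = tuple((d + 1) // 2 for d in cur)
        return shapes

    def forward(self, x: Tensor, injected: dict[int, np.ndarray] | None = None,
                capture: bool = False) -> Tensor:
        """Returns the (B,) logit tensor; ``injected`` maps stage -> batch
        feature arrays already resampled to the block input resolution."""
        if self.config.injected_stages and not injected:
            raise ValueError(
                f"variant {self.config.variant!r} requires injected features"
            )
        self.activations = {}
        h = self.stem_norm(self.stem(x)).relu()
        if capture:
            self.activations["stem"] = h
        for b, block in enumerate(self.blocks, start=1):
            if b in self.config.injected_stages:
                feats = injected[b]
                if feats.shape[2:] != h.shape[2:]:
                    raise ValueError(
                        f"stage {b} features {feats.shape[2:]} not at block "
                        f"input resolution {h.shape[2:]}"
                    )
                h = concat([h, Tensor(feats)], axis=1)
            h = block(h)
            if capture:
                self.activations[f"block{b}"] = h
        pooled = global_avg_pool(h)
        return self.head(pooled).reshape(-1)


def build_classifier(config: ClassifierConfig,
                     pyramid_channel_spec: dict[int, int] | None = None) -> Classifier3D:
    """Construct a variant; ``pyramid_channel_spec`` maps stage -> channels
    and is required for every injected stage."""
    return Classifier3D(config, pyramid_channel_spec or {})


def prepare_injection(model: Classifier3D, pyramid: FeaturePyramid,
                      input_spatial) -> dict[int, np.ndarray]:
    """Resample (trilinear) and per-channel z-score the injected stages to
    their block input resolutions. Spatial dims change; channels never do."""
    shapes = model.block_input_shapes(input_spatial)
    out = {}
    for s in sorted(model.config.injected_stages):
        feats = pyramid.stage(s).astype(np.float32)
        target = shapes[s - 1]
        resampled = np.empty((feats.shape[0],) + tuple(target), dtype=np.float32)
        for c in range(feats.shape[0]):
            resampled[c] = trilinear_resize(feats[c], target)
        mu = resampled.mean(axis=(1, 2, 3), keepdims=True)
        sd = resampled.std(axis=(1, 2, 3), keepdims=True)
        out[s] = (resampled - mu) / np.maximum(sd, 1e-6)
    return out
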