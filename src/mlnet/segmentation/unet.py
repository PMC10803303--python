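"""Miniature deep-supervised 3D U-Net.

Encoder stages double channels and halve resolution (stride-2 convolution);
the decoder upsamples, concatenates the encoder skip and refines. One 1x1x1
auxiliary head per decoder stage (the bottleneck included) provides the
deep-supervision logits. Decoder stage outputs are the feature pyramid
consumed by the classifier.
"""

from __future__ import annotations

import numpy as np

from ..nn import Conv3d, InstanceNorm3d, Module, Tensor, concat, upsample_nearest2
from .types import FeaturePyramid, UNetConfig

__all__ = ["ConvBlock", "UNet3D", "build_unet"]


class ConvBlock(Module):
    """(conv3 -> instance norm -> ReLU) x n; first conv may stride."""

    def __init__(self, in_ch: int, out_ch: int, n_convs: int, rng, stride: int = 1):
        self.convs = []
        self.norms = []
        for i in range(n_convs):
            self.convs.append(
                Conv3d(in_ch if i == 0 else out_ch, out_ch, k=3,
                       stride=stride if i == 0 else 1, rng=rng)
            )
            self.norms.append(InstanceNorm3d(out_ch))

    def forward(self, x: Tensor) -> Tensor:
        for conv, norm in zip(self.convs, self.norms):
            x = norm(conv(x)).relu()
        return x


class UNet3D(Module):
    def __init__(self, config: UNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        S = config.n_stages
        ch = config.stage_channels
        nc = config.convs_per_stage

        self.encoders = []
        for s in range(S):
            in_ch = config.input_channels if s == 0 else ch[s - 1]
            self.encoders.append(ConvBlock(in_ch, ch[s], nc, rng,
                                           stride=1 if s == 0 else 2))
        self.decoders = []  # for stages S-1 .. 1 (finer and finer)
        for s in range(S - 2, -1, -1):
            self.decoders.append(ConvBlock(ch[s + 1] + ch[s], ch[s], nc, rng))
        self.heads = [Conv3d(ch[s], 1, k=1, rng=rng) for s in range(S)]
        for head in self.heads:  # background-prior bias speeds early training
            head.bias.data[:] = -2.0

    def forward(self, x: Tensor):
        """Returns (logits, features), both lists indexed stage-1-first."""
        S = self.config.n_stages
        min_dim = min(x.shape[2:])
        if min_dim < 2 ** (S - 1):
            raise ValueError(
                f"input spatial dims {x.shape[2:]} too small for {S} stages "
                f"(need >= {2 ** (S - 1)} per axis)"
            )
        if x.shape[1] != self.config.input_channels:
            raise ValueError(
                f"expected {self.config.input_channels} channels, got {x.shape[1]}"
            )
        enc = []
        h = x
        for encoder in self.encoders:
            h = encoder(h)
            enc.append(h)
        features = [None] * S
        features[S - 1] = enc[-1]  # bottleneck = coarsest stage
        h = enc[-1]
        for i, decoder in enumerate(self.decoders):
            s = S - 2 - i  # 0-based target stage
            up = upsample_nearest2(h)
            up = _crop_to(up, enc[s].shape)
            h = decoder(concat([up, enc[s]], axis=1))
            features[s] = h
        logits = [self.heads[s](features[s]) for s in range(S)]
        return logits, features


def _crop_to(t: Tensor, ref_shape) -> Tensor:
    """Crop trailing voxels after x2 upsampling of an odd-sized stage."""
    if t.shape[2:] == ref_shape[2:]:
        return t
    d, h, w = ref_shape[2], ref_shape[3], ref_shape[4]
    out = Tensor(np.ascontiguousarray(t.data[:, :, :d, :h, :w]))
    out._parents = (t,)

    def _bw(g):
        gg = np.zeros(t.shape, dtype=np.float32)
        gg[:, :, :d, :h, :w] = g
        t._accumulate(gg)

    out._backward = _bw
    return out


def build_unet(config: UNetConfig) -> UNet3D:
    """Deterministically initialised deep-supervised U-Net."""
    return UNet3D(config)
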