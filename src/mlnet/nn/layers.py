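"""Neural-network building blocks for 3D volumes (numpy backend).

Convolution is im2col + BLAS sgemm, which is where essentially all the
compute goes; everything here is single-threaded and deterministic.
"""

from __future__ import annotations

import numpy as np

from .tensor import Parameter, Tensor, _sigmoid

__all__ = [
    "Module",
    "Conv3d",
    "InstanceNorm3d",
    "Linear",
    "upsample_nearest2",
    "global_avg_pool",
    "bce_with_logits",
    "soft_dice_loss",
]


class Module:
    """Base class: parameter traversal and flat state dicts."""

    def named_parameters(self, prefix: str = ""):
        for key, val in vars(self).items():
            name = f"{prefix}{key}"
            if isinstance(val, Parameter):
                yield name, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{name}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{name}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state dict keys do not match module: {sorted(missing)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


# --------------------------------------------------------------------- conv3d


def _offset_slices(k: int, stride: int, out_sp):
    Do, Ho, Wo = out_sp
    for a in range(k):
        for b in range(k):
            for c in range(k):
                yield (
                    slice(a, a + Do * stride, stride),
                    slice(b, b + Ho * stride, stride),
                    slice(c, c + Wo * stride, stride),
                )


def _shift_slab(xp: np.ndarray, sl, buf: np.ndarray) -> np.ndarray:
    """Copy one kernel-offset slab into a reused contiguous buffer, returned
    as (B, C, P). Avoids materialising the full k^3-times-larger im2col
    matrix (which would dominate memory traffic at 3D volume sizes)."""
    np.copyto(buf, xp[:, :, sl[0], sl[1], sl[2]])
    return buf.reshape(buf.shape[0], buf.shape[1], -1)


class Conv3d(Module):
    """3D convolution, cubic kernel, 'same'-style padding = k//2."""

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, bias: bool = True):
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * k**3
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, k, stride
        self.pad = k // 2
        self.weight = Parameter(rng.normal(0.0, scale, (out_ch, in_ch, k, k, k)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        B, C, D, H, W = x.shape
        if C != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {C}")
        k, st, pad = self.k, self.stride, self.pad
        out_sp = tuple((s + 2 * pad - k) // st + 1 for s in (D, H, W))
        xp = np.pad(x.data, ((0, 0), (0, 0)) + ((pad, pad),) * 3) if pad else x.data
        P = out_sp[0] * out_sp[1] * out_sp[2]
        w3 = self.weight.data.reshape(self.out_ch, C, k**3)  # kernel offset last
        offsets = list(_offset_slices(k, st, out_sp))
        buf = np.empty((B, C) + out_sp, dtype=np.float32)
        y = np.zeros((B, self.out_ch, P), dtype=np.float32)
        for j, sl in enumerate(offsets):
            y += np.matmul(w3[:, :, j], _shift_slab(xp, sl, buf))
        if self.bias is not None:
            y += self.bias.data[:, None]
        out = Tensor(y.reshape(B, self.out_ch, *out_sp))
        parents = [x, self.weight] + ([self.bias] if self.bias is not None else [])
        out._parents = tuple(parents)
        weight, bias = self.weight, self.bias

        def _bw(g):
            gmat = np.ascontiguousarray(g).reshape(B, self.out_ch, P)
            if bias is not None:
                bias._accumulate(gmat.sum(axis=(0, 2)))
            dw3 = np.empty_like(w3)
            dxp = np.zeros_like(xp)
            bbuf = np.empty((B, C) + out_sp, dtype=np.float32)
            for j, sl in enumerate(offsets):
                xs = _shift_slab(xp, sl, bbuf)
                dw3[:, :, j] = np.matmul(gmat, xs.transpose(0, 2, 1)).sum(axis=0)
                dxs = np.matmul(w3[:, :, j].T, gmat)
                dxp[:, :, sl[0], sl[1], sl[2]] += dxs.reshape(B, C, *out_sp)
            weight._accumulate(dw3.reshape(weight.data.shape))
            dx = dxp[:, :, pad:-pad, pad:-pad, pad:-pad] if pad else dxp
            x._accumulate(np.ascontiguousarray(dx))

        out._backward = _bw
        return out


# ------------------------------------------------------------- normalisation


class InstanceNorm3d(Module):
    """Per-sample, per-channel normalisation over the spatial axes.

    Chosen over batch norm: no train/eval mode split, no running statistics,
    deterministic at any batch size.
    """

    def __init__(self, ch: int, eps: float = 1e-5):
        self.ch = ch
        self.eps = eps
        self.gamma = Parameter(np.ones(ch))
        self.beta = Parameter(np.zeros(ch))

    def forward(self, x: Tensor) -> Tensor:
        ax = (2, 3, 4)
        mu = x.data.mean(axis=ax, keepdims=True)
        var = x.data.var(axis=ax, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * inv
        gb = self.gamma.data.reshape(1, -1, 1, 1, 1)
        out = Tensor(gb * xhat + self.beta.data.reshape(1, -1, 1, 1, 1))
        out._parents = (x, self.gamma, self.beta)
        gamma, beta = self.gamma, self.beta
        n = x.data.shape[2] * x.data.shape[3] * x.data.shape[4]

        def _bw(g):
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3, 4)))
            beta._accumulate(g.sum(axis=(0, 2, 3, 4)))
            dxhat = g * gb
            m1 = dxhat.mean(axis=ax, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=ax, keepdims=True)
            x._accumulate(inv * (dxhat - m1 - xhat * m2))

        out._backward = _bw
        return out


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(1.0 / in_f)
        self.weight = Parameter(rng.normal(0.0, scale, (out_f, in_f)))
        self.bias = Parameter(np.zeros(out_f))

    def forward(self, x: Tensor) -> Tensor:
        out = Tensor(x.data @ self.weight.data.T + self.bias.data)
        out._parents = (x, self.weight, self.bias)
        weight, bias = self.weight, self.bias

        def _bw(g):
            weight._accumulate(g.T @ x.data)
            bias._accumulate(g.sum(axis=0))
            x._accumulate(g @ weight.data)

        out._backward = _bw
        return out


# ------------------------------------------------------------------ resizing


def upsample_nearest2(x: Tensor) -> Tensor:
    """Nearest-neighbour x2 upsampling of a (B, C, D, H, W) tensor."""
    d = x.data
    up = d.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)
    out = Tensor(up)
    out._parents = (x,)
    B, C, D, H, W = d.shape

    def _bw(g):
        g = g.reshape(B, C, D, 2, H, 2, W, 2).sum(axis=(3, 5, 7))
        x._accumulate(g)

    out._backward = _bw
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """(B, C, D, H, W) -> (B, C) spatial mean."""
    d = x.data
    n = d.shape[2] * d.shape[3] * d.shape[4]
    out = Tensor(d.mean(axis=(2, 3, 4)))
    out._parents = (x,)

    def _bw(g):
        x._accumulate(
            np.broadcast_to(g[:, :, None, None, None] / n, d.shape).astype(np.float32)
        )

    out._backward = _bw
    return out


# -------------------------------------------------------------------- losses


def bce_with_logits(logits: Tensor, targets: np.ndarray, pos_weight: float = 1.0) -> Tensor:
    """Mean binary cross-entropy on logits; positives weighted by pos_weight.

    With pos_weight == 1 this is the plain unweighted BCE.
    """
    z = logits.data
    t = np.asarray(targets, dtype=np.float32)
    if t.shape != z.shape:
        raise ValueError(f"target shape {t.shape} != logits shape {z.shape}")
    w = np.float32(pos_weight)
    # log(1+e^-|z|) + max(z,0) - z*t, with the positive term weighted
    softplus_neg = np.logaddexp(0.0, -np.abs(z))
    per = w * t * (softplus_neg + np.maximum(-z, 0.0)) + (1.0 - t) * (
        softplus_neg + np.maximum(z, 0.0)
    )
    n = per.size
    out = Tensor(per.mean())
    out._parents = (logits,)
    s = _sigmoid(z)

    def _bw(g):
        logits._accumulate(g * (w * t * (s - 1.0) + (1.0 - t) * s) / n)

    out._backward = _bw
    return out


def soft_dice_loss(logits: Tensor, targets: np.ndarray, eps: float = 1.0) -> Tensor:
    """1 - soft Dice between sigmoid(logits) and targets in [0, 1]."""
    z = logits.data
    t = np.asarray(targets, dtype=np.float32)
    if t.shape != z.shape:
        raise ValueError(f"target shape {t.shape} != logits shape {z.shape}")
    p = _sigmoid(z)
    inter = float((p * t).sum())
    denom = float(p.sum() + t.sum()) + eps
    dice = (2.0 * inter + eps) / denom
    out = Tensor(np.float32(1.0 - dice))
    out._parents = (logits,)

    def _bw(g):
        # d(1-dice)/dp = -(2*t*denom - (2*inter+eps)) / denom^2
        dp = -(2.0 * t * denom - (2.0 * inter + eps)) / denom**2
        logits._accumulate(g * dp * p * (1.0 - p))

    out._backward = _bw
    return out
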