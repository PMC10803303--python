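"""Optimisers: Adam and a sharpness-aware (SAM) wrapper.

SAM takes one ascent step of size rho along the normalised gradient,
re-evaluates the gradient at the perturbed point, restores the original
parameters and applies the base optimiser step with the perturbed gradient.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .tensor import Parameter, Tensor

__all__ = ["Adam", "SAM"]


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)


class SAM:
    """Sharpness-aware minimisation around a base optimiser.

    ``step(closure)`` expects ``closure`` to zero gradients, run the
    forward/backward pass and return the loss tensor. With rho == 0 (or a
    vanishing gradient) the behaviour reduces exactly to the base step.
    """

    def __init__(self, base: Adam, rho: float = 0.05):
        if rho < 0:
            raise ValueError("rho must be >= 0")
        self.base = base
        self.rho = rho
        self.params = base.params

    def zero_grad(self) -> None:
        self.base.zero_grad()

    def _grad_norm(self) -> float:
        sq = 0.0
        for p in self.params:
            if p.grad is not None:
                sq += float((p.grad.astype(np.float64) ** 2).sum())
        return float(np.sqrt(sq))

    def step(self, closure: Callable[[], Tensor]) -> Tensor:
        loss = closure()
        norm = self._grad_norm()
        if self.rho == 0.0 or norm == 0.0:
            # degenerate case: plain base step with the current gradient
            self.base.step()
            return loss
        scale = self.rho / norm
        eps_steps = []
        for p in self.params:
            e = (p.grad * scale).astype(np.float32) if p.grad is not None else None
            eps_steps.append(e)
            if e is not None:
                p.data += e
        closure()  # gradient at the perturbed point
        for p, e in zip(self.params, eps_steps):
            if e is not None:
                p.data -= e
        self.base.step()
        return loss
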