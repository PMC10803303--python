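"""Functional sharpness-aware update: the two-step procedure on raw arrays.

The training loop uses the optimiser wrapper in ``mlnet.nn.optim``; this
standalone form exposes the identical arithmetic for direct inspection:
ascend to w + rho * g / ||g||, take the gradient there, then apply the base
step from the ORIGINAL parameters with that perturbed gradient.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["sam_update"]


def sam_update(loss_surface: Callable, parameters, rho: float, base_step) -> np.ndarray:
    """One SAM update.

    loss_surface(params) must return the gradient array (or a (loss, grad)
    tuple). ``base_step`` is either a scalar learning rate (plain gradient
    descent) or a callable (params, grad) -> new params. A zero gradient
    norm falls back to the plain base step.
    """
    if rho < 0:
        raise ValueError("rho must be >= 0")
    params = np.asarray(parameters, dtype=np.float64)

    def grad_at(w):
        out = loss_surface(w)
        if isinstance(out, tuple):
            out = out[1]
        return np.asarray(out, dtype=np.float64)

    def apply_base(w, g):
        if callable(base_step):
            return np.asarray(base_step(w, g), dtype=np.float64)
        return w - float(base_step) * g

    g = grad_at(params)
    norm = float(np.linalg.norm(g))
    if rho == 0.0 or norm == 0.0:
        return apply_base(params, g)
    g_perturbed = grad_at(params + rho * g / norm)
    return apply_base(params, g_perturbed)
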