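"""Trilinear resizing helpers (no gradient flows through these)."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = ["trilinear_resize", "trilinear_rescale"]


def trilinear_resize(vol: np.ndarray, out_shape: tuple[int, int, int]) -> np.ndarray:
    """Resize a 3D array with trilinear interpolation, voxel-centre aligned.

    Output voxel j samples the input at (j + 0.5) * (n_in / n_out) - 0.5,
    clamped at the edges (the convention of standard deep-learning trilinear
    interpolation without corner alignment).
    """
    vol = np.asarray(vol, dtype=np.float32)
    if vol.ndim != 3:
        raise ValueError("expected a 3D array")
    if vol.shape == tuple(out_shape):
        return vol.copy()
    grids = []
    for n_in, n_out in zip(vol.shape, out_shape):
        scale = n_in / n_out
        grids.append((np.arange(n_out, dtype=np.float64) + 0.5) * scale - 0.5)
    coords = np.meshgrid(*grids, indexing="ij")
    out = map_coordinates(vol.astype(np.float64), coords, order=1, mode="nearest")
    return out.astype(np.float32)


def trilinear_rescale(vol: np.ndarray, factor: float) -> np.ndarray:
    """Resize by a uniform scale factor (e.g. 0.5 to halve every axis)."""
    out_shape = tuple(max(1, int(round(s * factor))) for s in vol.shape)
    return trilinear_resize(vol, out_shape)
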