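"""Spacing-based trilinear resampling of volumes onto a new grid."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

from .types import BinaryMask, VolumeImage

__all__ = ["resample_to_grid", "resample_mask_to_grid"]


def _target_shape(shape, src_spacing, dst_spacing):
    # largest grid whose sample points stay inside the source extent
    return tuple(
        int(np.floor((n - 1) * s_in / s_out)) + 1
        for n, s_in, s_out in zip(shape, src_spacing, dst_spacing)
    )


def _coords(out_shape, src_spacing, dst_spacing):
    grids = [
        np.arange(n, dtype=np.float64) * s_out / s_in
        for n, s_in, s_out in zip(out_shape, src_spacing, dst_spacing)
    ]
    return np.meshgrid(*grids, indexing="ij")


def resample_to_grid(volume: VolumeImage, target_spacing) -> VolumeImage:
    """Trilinearly resample onto a grid with ``target_spacing``.

    Sample points are index-aligned (world = origin + index * spacing), so
    identical spacing returns a voxel-identical copy and affine intensity
    fields are preserved exactly.
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target spacing must be positive")
    if target_spacing == volume.spacing:
        return VolumeImage(
            volume.data.copy(), volume.channel_names, volume.spacing, volume.origin
        )
    out_shape = _target_shape(volume.grid_shape, volume.spacing, target_spacing)
    coords = _coords(out_shape, volume.spacing, target_spacing)
    out = np.empty((volume.data.shape[0],) + out_shape, dtype=np.float32)
    for c in range(volume.data.shape[0]):
        out[c] = map_coordinates(
            volume.data[c].astype(np.float64), coords, order=1, mode="nearest"
        )
    return VolumeImage(out, volume.channel_names, target_spacing, volume.origin)


def resample_mask_to_grid(mask: BinaryMask, target_spacing) -> BinaryMask:
    """Masks are resampled nearest-neighbour (labels stay binary)."""
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target spacing must be positive")
    if target_spacing == mask.spacing:
        return BinaryMask(mask.data.copy(), mask.spacing)
    out_shape = _target_shape(mask.grid_shape, mask.spacing, target_spacing)
    coords = _coords(out_shape, mask.spacing, target_spacing)
    out = map_coordinates(mask.data, coords, order=0, mode="nearest")
    return BinaryMask(out, target_spacing)
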