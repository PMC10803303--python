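"""Domain types for synthetic multi-centre cohorts."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["VolumeImage", "BinaryMask", "CaseRecord", "CentreProfile", "PhantomSpec"]


@dataclass
class VolumeImage:
    """Multi-channel 3D scalar grid with physical spacing.

    ``data`` is (C, D, H, W); all channels share one grid. World coordinates
    follow world = origin + index * spacing, indices 0-based.
    """

    data: np.ndarray
    channel_names: tuple[str, ...] = ("DWI", "T2W")
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim == 3:
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValueError("image data must be (C, D, H, W)")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names must match number of channels")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be 3 positive reals")
        self.origin = tuple(float(o) for o in self.origin)
        if not np.isfinite(self.data).all():
            raise ValueError("image contains non-finite values")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_names.index(name)]


@dataclass
class BinaryMask:
    """Binary 3D mask on the same grid as its paired image."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        arr = np.asarray(self.data)
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be in {0, 1}")
        self.data = arr.astype(np.uint8)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def volume_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class CentreProfile:
    """Acquisition character of one centre: intensity gain, smooth bias
    field amplitude, noise level and voxel spacing."""

    centre_id: str
    gain: float = 1.0
    bias_amplitude: float = 0.0
    noise_sigma: float = 0.0
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)

    def __post_init__(self):
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.bias_amplitude < 0 or self.noise_sigma < 0:
            raise ValueError("bias_amplitude and noise_sigma must be >= 0")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")


@dataclass
class PhantomSpec:
    """Controls tumour geometry and the label-encoding signal.

    The EMVI-like label adds ``emvi_protrusions`` thin tubes extending beyond
    the tumour body (fine boundary-scale signal); the CR-like label modulates
    internal texture heterogeneity and overall size (coarse signal).
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    tumour_radius_range: tuple[float, float] = (4.5, 7.0)  # mm
    emvi_protrusions: tuple[int, float, float] = (4, 6.0, 1.4)  # count, length mm, radius mm
    cr_texture: float = 0.5
    channel_contrasts: tuple[float, ...] = (0.8, 0.45)  # tumour-background, per channel
    boundary_perturbation: float = 0.12  # per-case amplitude is drawn up to this
    protrusion_contrast: float = 1.0  # fraction of tumour contrast in the image

    def __post_init__(self):
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        if len(self.grid_shape) != 3 or any(g < 8 for g in self.grid_shape):
            raise ValueError("grid_shape must be 3 integers >= 8")
        lo, hi = self.tumour_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("tumour_radius_range must be a positive interval")
        count, length, radius = self.emvi_protrusions
        if count < 0 or length <= 0 or radius <= 0:
            raise ValueError("invalid protrusion parameters")
        if not 0.0 <= self.cr_texture <= 1.0:
            raise ValueError("cr_texture must lie in [0, 1]")


@dataclass
class CaseRecord:
    """One synthetic patient."""

    patient_id: str
    centre_id: str
    image: VolumeImage
    mask: BinaryMask
    emvi_label: int
    cr_label: int
    age: float
    sex: str
    cT: str
    cN: int
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.emvi_label not in (0, 1) or self.cr_label not in (0, 1):
            raise ValueError("labels must be binary")
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")
        if self.cT not in ("1-2", "3", "4"):
            raise ValueError("cT must be one of '1-2', '3', '4'")
        if self.cN not in (0, 1, 2):
            raise ValueError("cN must be 0, 1 or 2")
        if self.image.grid_shape != self.mask.grid_shape:
            raise ValueError("image and mask grids differ")
        if self.mask.volume_voxels() == 0:
            raise ValueError("mask must be nonempty")
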