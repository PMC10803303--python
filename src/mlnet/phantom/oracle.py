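"""Geometric oracles on generated masks.

These are deliberately independent of the generator internals: the base
ellipsoid is re-fitted from mask moments, so protrusion detection does not
peek at the ground-truth geometry.
"""

from __future__ import annotations

import numpy as np

from .types import BinaryMask

__all__ = ["fit_ellipsoid", "protrusion_voxel_count"]


def fit_ellipsoid(mask: BinaryMask):
    """Moment-fit an ellipsoid to a solid mask.

    Returns (centre_mm, radii_mm, rotation) where rotation columns are the
    principal axes. For a solid uniform ellipsoid the second moment along a
    principal axis is r^2 / 5.
    """
    idx = np.argwhere(mask.data > 0)
    if idx.size == 0:
        raise ValueError("empty mask")
    pts = idx * np.asarray(mask.spacing)
    centre = pts.mean(axis=0)
    cov = np.cov((pts - centre).T)
    if cov.ndim == 0:
        cov = np.eye(3) * float(cov)
    evals, evecs = np.linalg.eigh(cov)
    radii = np.sqrt(np.maximum(evals, 1e-9) * 5.0)
    return centre, radii, evecs


def protrusion_voxel_count(mask: BinaryMask, inflate: float = 1.2) -> int:
    """Number of mask voxels outside the fitted base ellipsoid.

    ``inflate`` grows the fitted radii to absorb boundary perturbation; thin
    protrusions extend well beyond it. This count is the trivial oracle for
    the EMVI-like label.
    """
    centre, radii, rot = fit_ellipsoid(mask)
    idx = np.argwhere(mask.data > 0)
    pts = idx * np.asarray(mask.spacing) - centre
    local = pts @ rot  # into principal axes
    d = np.sqrt(((local / (radii * inflate)) ** 2).sum(axis=1))
    return int((d > 1.0).sum())
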