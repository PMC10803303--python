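"""Synthetic tumour phantom generation.

Each case is an anisotropic ellipsoid with a smooth boundary perturbation.
The EMVI-like label adds thin tubular protrusions that extend beyond the
tumour body (a fine, boundary-scale signal); the CR-like label shrinks the
tumour and damps its internal texture (a coarse signal). The second channel
is synthesised on a twice-finer grid and trilinearly resampled onto the
first channel's grid, mimicking T2W-onto-DWI preprocessing.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .resample import resample_to_grid
from .types import BinaryMask, CaseRecord, CentreProfile, PhantomSpec, VolumeImage

__all__ = ["generate_case", "generate_cohort", "apply_centre_shift"]

# positive boundary-perturbation clip: keeps EMVI-negative masks inside the
# moment-fitted base ellipsoid inflated by ~1.3 (the containment oracle)
_PERT_CLIP = 0.20

_CT_LEVELS = ("1-2", "3", "4")
_CT_PROBS = (0.07, 0.81, 0.12)
_CN_PROBS = (0.13, 0.24, 0.63)
_P_FEMALE = 0.35


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Zero-mean, unit-std smooth random field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    sd = f.std()
    if sd < 1e-12:
        return np.zeros(shape, dtype=np.float64)
    return (f - f.mean()) / sd


def _mm_axes(shape, spacing):
    return [np.arange(n, dtype=np.float64) * s for n, s in zip(shape, spacing)]


def _ellipsoid_distance(axes, centre, radii) -> np.ndarray:
    zz = (axes[0] - centre[0]) / radii[0]
    yy = (axes[1] - centre[1]) / radii[1]
    xx = (axes[2] - centre[2]) / radii[2]
    return np.sqrt(
        zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
    )


def _segment_distance(axes, p0, p1) -> np.ndarray:
    """Distance (mm) from every voxel centre to the segment p0-p1."""
    grid = np.stack(
        np.meshgrid(*axes, indexing="ij"), axis=-1
    )  # (D, H, W, 3) in mm
    d = p1 - p0
    len2 = float(d @ d)
    t = ((grid - p0) @ d) / max(len2, 1e-12)
    t = np.clip(t, 0.0, 1.0)
    proj = p0 + t[..., None] * d
    return np.linalg.norm(grid - proj, axis=-1)


def _tumour_geometry(spec: PhantomSpec, profile: CentreProfile, emvi: int, cr: int,
                     rng: np.random.Generator):
    shape = spec.grid_shape
    spacing = profile.spacing
    extent = np.array([(n - 1) * s for n, s in zip(shape, spacing)])

    r_base = rng.uniform(*spec.tumour_radius_range)
    size_factor = 1.0 - 0.18 * cr  # CR-like tumours are smaller
    radii = r_base * size_factor * rng.uniform(0.85, 1.15, size=3)
    centre = extent / 2.0 + rng.uniform(-0.06, 0.06, size=3) * extent

    count, length, prot_radius = spec.emvi_protrusions
    margin = radii.max() * (1.0 + _PERT_CLIP)
    if emvi:
        margin += 1.15 * length + prot_radius  # 1.15 = max length jitter
    if (centre - margin < 0).any() or (centre + margin > extent).any():
        raise ValueError(
            f"grid too small to contain tumour: radius {r_base:.1f} mm plus "
            f"margins exceeds the grid extent {extent} mm"
        )

    # protrusion axes: fixed directions spread over the sphere, jittered
    directions = []
    if emvi:
        for _ in range(count):
            v = rng.standard_normal(3)
            directions.append(v / np.linalg.norm(v))
    return centre, radii, directions


def generate_case(spec: PhantomSpec, profile: CentreProfile, emvi: int, cr: int,
                  seed: int) -> CaseRecord:
    """Generate one deterministic phantom case."""
    if emvi not in (0, 1) or cr not in (0, 1):
        raise ValueError("emvi and cr must be 0 or 1")
    rng = np.random.default_rng(seed)
    shape = spec.grid_shape
    spacing = profile.spacing
    centre, radii, directions = _tumour_geometry(spec, profile, emvi, cr, rng)

    # per-case nuisance: smooth boundary irregularity of random amplitude and
    # scale, label-independent — coarse shape statistics vary in both classes
    pert_amp = rng.uniform(0.25, 1.0) * spec.boundary_perturbation
    pert_sigma = rng.uniform(2.0, 4.0)

    axes = _mm_axes(shape, spacing)
    dist = _ellipsoid_distance(axes, centre, radii)
    pert = pert_amp * _smooth_field(rng, shape, sigma=pert_sigma)
    pert = np.clip(pert, -_PERT_CLIP, _PERT_CLIP)
    core = dist <= 1.0 + pert

    count, length, prot_radius = spec.emvi_protrusions
    lengths = length * rng.uniform(0.8, 1.15, size=max(count, 1))
    prot = np.zeros(shape, dtype=bool)
    for u, li in zip(directions, lengths):
        # surface point along u, then extend outward by the tube length
        t_surf = 1.0 / np.sqrt(((u / radii) ** 2).sum())
        p0 = centre + 0.85 * t_surf * u
        p1 = centre + (t_surf + li) * u
        prot |= _segment_distance(axes, p0, p1) <= prot_radius
    mask = core | prot

    tex_amp = 0.35 * spec.cr_texture * (1.0 - 0.7 * cr)  # CR-like: homogeneous
    contrast_jitter = rng.uniform(0.75, 1.05)  # per-case acquisition nuisance
    noise_seed = int(rng.integers(0, 2**31))

    def _paint(grid_shape, grid_spacing, chan_rng):
        ax = _mm_axes(grid_shape, grid_spacing)
        d = _ellipsoid_distance(ax, centre, radii)
        p = pert_amp * _smooth_field(chan_rng, grid_shape, sigma=pert_sigma)
        c = d <= 1.0 + np.clip(p, -_PERT_CLIP, _PERT_CLIP)
        pr = np.zeros(grid_shape, dtype=bool)
        for u, li in zip(directions, lengths):
            t_surf = 1.0 / np.sqrt(((u / radii) ** 2).sum())
            pr |= (
                _segment_distance(ax, centre + 0.85 * t_surf * u, centre + (t_surf + li) * u)
                <= prot_radius
            )
        return ax, c, pr

    channels = []
    for k, base_contrast in enumerate(spec.channel_contrasts):
        contrast = base_contrast * contrast_jitter
        chan_rng = np.random.default_rng(noise_seed + k)
        if k == 0:
            grid_shape, grid_spacing = shape, spacing
            c, pr = core, prot
        else:
            # finer native grid, resampled back onto the reference grid below
            grid_shape = tuple(2 * n - 1 for n in shape)
            grid_spacing = tuple(s / 2.0 for s in spacing)
            _, c, pr = _paint(grid_shape, grid_spacing, chan_rng)
        img = 0.25 + 0.10 * _smooth_field(chan_rng, grid_shape, sigma=4.0)
        tex = _smooth_field(chan_rng, grid_shape, sigma=1.5)
        img = img + c * contrast * (1.0 + tex_amp * tex)
        img = img + (pr & ~c) * contrast * spec.protrusion_contrast
        if k == 0:
            channels.append(img.astype(np.float32))
        else:
            fine = VolumeImage(img.astype(np.float32)[None], ("fine",), grid_spacing)
            channels.append(resample_to_grid(fine, spacing).data[0])

    names = ("DWI", "T2W", "CH2", "CH3")[: len(channels)]
    image = VolumeImage(np.stack(channels), names, spacing)
    image = apply_centre_shift(image, profile, seed=int(rng.integers(0, 2**31)))

    age = float(np.clip(np.round(rng.normal(64.0, 12.0)), 25, 87))
    sex = "F" if rng.random() < _P_FEMALE else "M"
    cT = _CT_LEVELS[rng.choice(3, p=_CT_PROBS)]
    cN = int(rng.choice(3, p=_CN_PROBS))

    return CaseRecord(
        patient_id=f"case-{seed}",
        centre_id=profile.centre_id,
        image=image,
        mask=BinaryMask(mask.astype(np.uint8), spacing),
        emvi_label=int(emvi),
        cr_label=int(cr),
        age=age,
        sex=sex,
        cT=cT,
        cN=cN,
        meta={
            "ellipsoid_centre_mm": centre.tolist(),
            "ellipsoid_radii_mm": radii.tolist(),
            "n_protrusions": len(directions),
            "seed": int(seed),
        },
    )


def apply_centre_shift(volume: VolumeImage, profile: CentreProfile, seed: int) -> VolumeImage:
    """gain * (volume + smooth bias field) + Gaussian noise, per channel.

    An identity profile (gain 1, zero bias and noise) returns a
    voxel-identical volume.
    """
    rng = np.random.default_rng(seed)
    out = volume.data.copy()
    shape = volume.grid_shape
    for c in range(out.shape[0]):
        v = out[c].astype(np.float64)
        if profile.bias_amplitude > 0:
            v = v + profile.bias_amplitude * _smooth_field(
                rng, shape, sigma=max(shape) / 6.0
            )
        if profile.gain != 1.0:
            v = v * profile.gain
        if profile.noise_sigma > 0:
            v = v + rng.normal(0.0, profile.noise_sigma, size=shape)
        out[c] = v.astype(np.float32)
    return VolumeImage(out, volume.channel_names, volume.spacing, volume.origin)


def default_centres(n: int = 9, seed: int = 0) -> list[CentreProfile]:
    """A spread of centre profiles emulating scanner/protocol heterogeneity."""
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n):
        profiles.append(
            CentreProfile(
                centre_id=f"C{i + 1}",
                gain=float(rng.uniform(0.8, 1.25)),
                bias_amplitude=float(rng.uniform(0.0, 0.08)),
                noise_sigma=float(rng.uniform(0.02, 0.07)),
                spacing=(1.5, 1.5, 1.5),
            )
        )
    return profiles


def generate_cohort(n: int, centres: list[CentreProfile], p_emvi: float, p_cr: float,
                    seed: int, spec: PhantomSpec | None = None) -> list[CaseRecord]:
    """Generate a reproducible multi-centre cohort.

    Centres are assigned round-robin (every centre is used when n >= number
    of centres) and the order is then shuffled; labels are independent
    Bernoulli draws.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not centres:
        raise ValueError("at least one centre profile is required")
    if not (0.0 <= p_emvi <= 1.0 and 0.0 <= p_cr <= 1.0):
        raise ValueError("prevalences must lie in [0, 1]")
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    order = [centres[i % len(centres)] for i in range(n)]
    rng.shuffle(order)
    emvi = (rng.random(n) < p_emvi).astype(int)
    cr = (rng.random(n) < p_cr).astype(int)
    case_seeds = rng.integers(0, 2**31, size=n)
    cases = []
    for i in range(n):
        case = generate_case(spec, order[i], int(emvi[i]), int(cr[i]), int(case_seeds[i]))
        case.patient_id = f"P{i + 1:04d}"
        cases.append(case)
    return cases
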