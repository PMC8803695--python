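"""Multiplanar-reformation (MPR) feature extraction.

The network input for one uptake region is a stack of thirteen coronal
planes sampled from the 3 mm isotropic PET/CT volume around the region's
SUVmax position, at fixed anterior-posterior offsets

    (-144, -96, -48, -24, -12, -6, 0, +6, +12, +24, +48, +96, +144) mm,

each plane covering 192 mm x 192 mm at the 3 mm grid resolution (64 x 64
samples).  PET is windowed to [0, 15] SUV and CT to [-300, 300] HU, both
mapped affinely to [0, 1]; samples outside the volume take the window
minimum (0 after normalization).

Affine augmentation re-extracts the stack after applying a random isotropic
scaling (0.8-1.2) and rotations (±17.2° about each patient axis, applied
extrinsically in x → y → z order) about the centre position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from petstage.errors import GeometryError
from petstage.io_volumes import PetCtVolume

MPR_OFFSETS_MM: tuple[float, ...] = (
    -144.0, -96.0, -48.0, -24.0, -12.0, -6.0, 0.0, 6.0, 12.0, 24.0, 48.0, 96.0, 144.0,
)
PLANE_SIZE = 64          # samples per in-plane axis (192 mm at 3 mm)
GRID_MM = 3.0
PET_WINDOW = (0.0, 15.0)
CT_WINDOW = (-300.0, 300.0)

SCALE_RANGE = (0.8, 1.2)
ROTATION_DEG = 17.2


@dataclass
class MprStack:
    """13 x 2 x 64 x 64 feature stack; channel axis order (PET, CT)."""

    planes: np.ndarray
    offsets_mm: tuple[float, ...]
    center_voxel: tuple[int, int, int]

    def as_network_input(self) -> np.ndarray:
        """Stack planes and modalities as 26 input channels (float32)."""
        return self.planes.reshape(26, PLANE_SIZE, PLANE_SIZE)


def _base_offsets() -> np.ndarray:
    """Fixed voxel-space sampling offsets, shape (3, 13*64*64).

    In-plane axes are grid axis 0 (left-right) and axis 2
    (inferior-superior), samples at index center + (k - 32); the plane axis
    is grid axis 1 (anterior-posterior) at the fixed mm offsets.  At 3 mm
    isotropic spacing voxel offsets are mm offsets / 3.
    """
    half = np.arange(PLANE_SIZE, dtype=np.float64) - PLANE_SIZE // 2
    off_vox = np.asarray(MPR_OFFSETS_MM, dtype=np.float64) / GRID_MM
    u, o, w = np.meshgrid(half, off_vox, half, indexing="ij")  # u: LR, w: IS
    return np.stack([u.ravel(), o.ravel(), w.ravel()], axis=0)


_BASE_OFFSETS = _base_offsets()
_SAMPLE_GRID = (PLANE_SIZE, 13, PLANE_SIZE)


def _padded_channels(vol: PetCtVolume) -> np.ndarray:
    """PET/CT interleaved with a one-voxel fill border, cached on the volume.

    Padding with each channel's window minimum lets the sampler clamp
    coordinates to the border instead of masking: any sample whose
    interpolation window leaves the grid blends with the fill value, and
    samples fully outside return it exactly (constant-mode boundary
    handling).  Volumes are treated as immutable once extracted from.
    """
    cached = getattr(vol, "_mpr_padded", None)
    if cached is not None:
        return cached
    shape = vol.pet.shape
    # one fill voxel below, two above: coordinates clamped to [-1, n] then
    # read corners f..f+1 entirely inside the padded frame
    pshape = (shape[0] + 3, shape[1] + 3, shape[2] + 3)
    pet = np.full(pshape, PET_WINDOW[0], dtype=np.float32)
    ct = np.full(pshape, CT_WINDOW[0], dtype=np.float32)
    pet[1:-2, 1:-2, 1:-2] = vol.pet
    ct[1:-2, 1:-2, 1:-2] = vol.ct
    cached = (pet.ravel(), ct.ravel(), pshape)
    object.__setattr__(vol, "_mpr_padded", cached)
    return cached


def _trilinear_pair(vol: PetCtVolume, coords):
    """Trilinear sampling of both channels at shared voxel coordinates.

    Corner indices and weights are computed once and applied to both
    channels; coordinates may lie outside the grid (they fill with the
    channel window minimum, matching constant-mode boundary handling).
    """
    petf, ctf, pshape = _padded_channels(vol)
    shape = vol.pet.shape
    s0 = pshape[1] * pshape[2]
    s1 = pshape[2]
    c0 = np.clip(coords[0], -1.0, shape[0]).astype(np.float32)
    c1 = np.clip(coords[1], -1.0, shape[1]).astype(np.float32)
    c2 = np.clip(coords[2], -1.0, shape[2]).astype(np.float32)
    f0 = np.floor(c0)
    f1 = np.floor(c1)
    f2 = np.floor(c2)
    d0 = c0 - f0
    d1 = c1 - f1
    d2 = c2 - f2
    # +1 shifts into the padded frame
    base = (f0.astype(np.int64) + 1) * s0 + (f1.astype(np.int64) + 1) * s1 + (
        f2.astype(np.int64) + 1
    )
    g0 = 1.0 - d0
    g1 = 1.0 - d1
    g2 = 1.0 - d2
    acc_pet = np.zeros(coords.shape[1], dtype=np.float32)
    acc_ct = np.zeros(coords.shape[1], dtype=np.float32)
    for wa, off_a in ((g0, 0), (d0, s0)):
        for wb, off_b in ((g1, 0), (d1, s1)):
            wab = wa * wb
            for wc, off_c in ((g2, 0), (d2, 1)):
                w = wab * wc
                idx = base + (off_a + off_b + off_c)
                acc_pet += w * np.take(petf, idx)
                acc_ct += w * np.take(ctf, idx)
    return acc_pet, acc_ct


def _extract(vol: PetCtVolume, center, matrix: np.ndarray) -> MprStack:
    if not vol.is_isotropic(GRID_MM):
        raise GeometryError(
            f"volume spacing {tuple(vol.spacing)} is not {GRID_MM} mm isotropic; "
            "run resample_isotropic first"
        )
    center = np.asarray(center, dtype=np.float64)
    if np.any(center < 0) or np.any(center >= np.asarray(vol.shape)):
        raise GeometryError(f"center {tuple(center)} outside grid {vol.shape}")
    coords = center[:, None] + matrix @ _BASE_OFFSETS
    grid = _SAMPLE_GRID
    pet, ct = _trilinear_pair(vol, coords)
    pet = pet.reshape(grid)
    ct = ct.reshape(grid)
    pet = np.clip(pet, *PET_WINDOW) / PET_WINDOW[1]
    ct = (np.clip(ct, *CT_WINDOW) - CT_WINDOW[0]) / (CT_WINDOW[1] - CT_WINDOW[0])
    # grid axes are (LR, plane, IS) -> planes array (plane, channel, LR, IS)
    planes = np.stack([pet, ct], axis=0).transpose(2, 0, 1, 3).astype(np.float32)
    return MprStack(
        planes=planes,
        offsets_mm=MPR_OFFSETS_MM,
        center_voxel=tuple(int(round(c)) for c in center),
    )


def extract_mpr(vol: PetCtVolume, center) -> MprStack:
    """Extract the 13-plane two-channel stack centred on ``center``."""
    return _extract(vol, center, np.eye(3))


def _rotation_matrix(angles_deg: np.ndarray) -> np.ndarray:
    """Extrinsic rotations about grid axes x, y, z applied in that order."""
    out = np.eye(3)
    for axis, ang in enumerate(np.deg2rad(angles_deg)):
        c, s = np.cos(ang), np.sin(ang)
        r = np.eye(3)
        i, j = [a for a in range(3) if a != axis]
        r[i, i] = c
        r[j, j] = c
        r[i, j] = -s
        r[j, i] = s
        out = r @ out
    return out


def augment_affine(
    vol: PetCtVolume,
    center,
    rng_seed: int | np.random.Generator,
    scale_range: tuple[float, float] = SCALE_RANGE,
    rotation_deg: float = ROTATION_DEG,
) -> MprStack:
    """Re-extract the stack under a random affine about the centre.

    Scale ~ Uniform(scale_range) and three rotation angles ~
    Uniform(-rotation_deg, +rotation_deg) are drawn from the seeded
    generator; with ``scale_range=(1, 1)`` and ``rotation_deg=0`` the output
    equals :func:`extract_mpr` bit-exactly.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    s = rng.uniform(*scale_range)
    angles = rng.uniform(-rotation_deg, rotation_deg, size=3)
    matrix = s * _rotation_matrix(angles)
    return _extract(vol, center, matrix)
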