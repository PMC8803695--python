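"""Reading, writing and resampling of co-registered PET/CT volume pairs.

Conventions
-----------
Grids are stored with axes ordered (left-right, anterior-posterior,
inferior-superior) in the patient LPS frame: increasing index 0 moves toward
the patient's left, index 1 toward posterior, index 2 toward superior.
Voxel indices are 0-based; world coordinates are millimetres.  NIfTI stores
an RAS+ affine, so the first two world axes are negated on load/save.

PET grids are in SUV (standardized uptake value, dimensionless); negative
reconstruction noise is clamped to zero at load time because every
downstream threshold assumes non-negative uptake.  CT grids are in
Hounsfield units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

from petstage.errors import FormatError, GeometryError, OrientationError

_LPS_AXCODES = ("L", "P", "S")
# RAS <-> LPS: negate the first two world axes.
_RAS2LPS = np.diag([-1.0, -1.0, 1.0, 1.0])


@dataclass
class PetCtVolume:
    """Co-registered PET (SUV) and CT (HU) grids with shared geometry.

    Attributes
    ----------
    pet, ct : np.ndarray
        Identically shaped 3-D float32 arrays, axes (LR, AP, IS).
    spacing : np.ndarray
        Per-axis voxel size in mm, all > 0.
    origin : np.ndarray
        World (LPS, mm) position of voxel (0, 0, 0).
    """

    pet: np.ndarray
    ct: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.pet = np.asarray(self.pet, dtype=np.float32)
        self.ct = np.asarray(self.ct, dtype=np.float32)
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if self.pet.ndim != 3 or self.ct.ndim != 3:
            raise FormatError("PET and CT grids must be 3-D")
        if self.pet.shape != self.ct.shape:
            raise GeometryError(
                f"PET shape {self.pet.shape} != CT shape {self.ct.shape}"
            )
        if not np.all(self.spacing > 0):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pet.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 ml = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    def is_isotropic(self, target_mm: float = 3.0, atol: float = 1e-6) -> bool:
        return bool(np.allclose(self.spacing, target_mm, atol=atol))


@dataclass
class Subject:
    """One imaging subject: volume, tracer tag and annotated findings.

    ``tracer`` is ``"PSMA"`` or ``"FDG"``; ``group`` tags the annotation
    scheme used for the subject ("A": all uptake sites annotated from seed
    clicks; "B": liver-referenced floor with at most 100 sites).
    """

    subject_id: str
    tracer: str
    volume: PetCtVolume
    findings: list = field(default_factory=list)
    group: str = "A"

    def __post_init__(self) -> None:
        if self.tracer not in ("PSMA", "FDG"):
            raise ValueError(f"tracer must be 'PSMA' or 'FDG', got {self.tracer!r}")
        if self.group not in ("A", "B"):
            raise ValueError(f"group must be 'A' or 'B', got {self.group!r}")


def _load_lps(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI file, reorient the grid to LPS axis order.

    Returns (data, affine) where affine maps voxel indices to LPS world mm.
    """
    img = nib.load(str(path))
    if img.ndim == 4 and img.shape[3] == 1:
        img = img.slicer[..., 0]
    if img.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {img.shape}")
    try:
        ornt = nib.orientations.io_orientation(img.affine)
        target = nib.orientations.axcodes2ornt(_LPS_AXCODES)
        xfm = nib.orientations.ornt_transform(ornt, target)
    except Exception as exc:  # pragma: no cover - nibabel raises on degenerate affines
        raise OrientationError(f"{path}: cannot determine patient axes: {exc}") from exc
    data = nib.orientations.apply_orientation(np.asanyarray(img.dataobj), xfm)
    affine_ras = img.affine @ nib.orientations.inv_ornt_aff(xfm, img.shape)
    affine_lps = _RAS2LPS @ affine_ras
    # After reorientation the rotation part must be close to diagonal;
    # strongly oblique acquisitions are not supported.
    rot = affine_lps[:3, :3]
    off = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off)) > 1e-3 * max(np.max(np.abs(np.diag(rot))), 1.0):
        raise OrientationError(
            f"{path}: oblique affine cannot be reconciled to patient axes"
        )
    if np.any(np.diag(rot) <= 0):
        raise OrientationError(f"{path}: reoriented affine has non-positive spacing")
    return np.asarray(data, dtype=np.float32), affine_lps


def _resample_to_grid(
    data: np.ndarray,
    affine_src: np.ndarray,
    affine_dst: np.ndarray,
    shape_dst: tuple[int, int, int],
    order: int = 1,
    cval: float = 0.0,
) -> np.ndarray:
    """Sample ``data`` (on affine_src) at the voxel centres of the dst grid."""
    # voxel_dst -> world -> voxel_src
    m = np.linalg.inv(affine_src) @ affine_dst
    ii, jj, kk = np.meshgrid(
        np.arange(shape_dst[0]), np.arange(shape_dst[1]), np.arange(shape_dst[2]),
        indexing="ij",
    )
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=0).reshape(4, -1)
    src = (m @ vox)[:3]
    out = map_coordinates(
        np.asarray(data, dtype=np.float64), src, order=order, mode="constant", cval=cval
    )
    return out.reshape(shape_dst).astype(np.float32)


def load_volume_pair(pet_path, ct_path) -> PetCtVolume:
    """Load a PET/CT pair from NIfTI files onto the PET grid.

    Both files are reoriented to LPS patient axes.  If the CT grid differs
    from the PET grid, the CT is resampled onto the PET grid with trilinear
    interpolation (out-of-field CT filled with air, -1000 HU).  Negative PET
    values are clamped to zero.
    """
    pet, aff_pet = _load_lps(pet_path)
    ct, aff_ct = _load_lps(ct_path)
    if ct.shape != pet.shape or not np.allclose(aff_ct, aff_pet, atol=1e-3):
        ct = _resample_to_grid(ct, aff_ct, aff_pet, pet.shape, order=1, cval=-1000.0)
    pet = np.clip(pet, 0.0, None)
    spacing = np.diag(aff_pet[:3, :3]).copy()
    origin = aff_pet[:3, 3].copy()
    return PetCtVolume(pet=pet, ct=ct, spacing=spacing, origin=origin)


def _lps_affine(vol: PetCtVolume) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(vol.spacing)
    aff[:3, 3] = vol.origin
    return aff


def save_volume_pair(vol: PetCtVolume, pet_path, ct_path) -> None:
    """Write the pair as NIfTI (RAS+ affine derived from the LPS geometry)."""
    aff_ras = _RAS2LPS @ _lps_affine(vol)  # involution: LPS -> RAS
    nib.save(nib.Nifti1Image(vol.pet.astype(np.float32), aff_ras), str(pet_path))
    nib.save(nib.Nifti1Image(vol.ct.astype(np.float32), aff_ras), str(ct_path))


def save_label_map(labels: np.ndarray, vol: PetCtVolume, path) -> None:
    """Write an integer label map sharing the volume's geometry."""
    aff_ras = _RAS2LPS @ _lps_affine(vol)
    nib.save(nib.Nifti1Image(labels.astype(np.int16), aff_ras), str(path))


def resample_isotropic(vol: PetCtVolume, target_mm: float = 3.0) -> PetCtVolume:
    """Resample both channels to an isotropic grid (default 3 mm).

    Trilinear interpolation is used for both PET and CT; the world extent is
    preserved to within one voxel and the origin is kept fixed.  Applying the
    operation twice at the same target spacing is a no-op up to float
    round-off.
    """
    if target_mm <= 0:
        raise GeometryError(f"target_mm must be > 0, got {target_mm}")
    for ax in range(3):
        if vol.shape[ax] < 2:
            raise GeometryError(
                f"axis {ax} is degenerate (size {vol.shape[ax]}); cannot resample"
            )
    if vol.is_isotropic(target_mm):
        return vol
    new_shape = tuple(
        max(2, int(round(vol.shape[ax] * vol.spacing[ax] / target_mm)))
        for ax in range(3)
    )
    aff_src = _lps_affine(vol)
    aff_dst = np.eye(4)
    aff_dst[:3, :3] = np.diag([target_mm] * 3)
    aff_dst[:3, 3] = vol.origin
    # 'nearest' edge handling would inflate the border; constant-0 would bleed
    # into it. Clamp sample coordinates to the source grid instead.
    m = np.linalg.inv(aff_src) @ aff_dst
    ii, jj, kk = np.meshgrid(
        np.arange(new_shape[0]), np.arange(new_shape[1]), np.arange(new_shape[2]),
        indexing="ij",
    )
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=0).reshape(4, -1)
    src = (m @ vox)[:3]
    for ax in range(3):
        np.clip(src[ax], 0, vol.shape[ax] - 1, out=src[ax])
    pet = map_coordinates(vol.pet.astype(np.float64), src, order=1).reshape(new_shape)
    ct = map_coordinates(vol.ct.astype(np.float64), src, order=1).reshape(new_shape)
    return PetCtVolume(
        pet=pet.astype(np.float32),
        ct=ct.astype(np.float32),
        spacing=np.array([target_mm] * 3),
        origin=vol.origin.copy(),
    )


def with_channels(vol: PetCtVolume, pet=None, ct=None) -> PetCtVolume:
    """Return a copy of ``vol`` with one or both channels replaced."""
    return replace(
        vol,
        pet=vol.pet if pet is None else pet,
        ct=vol.ct if ct is None else ct,
        spacing=vol.spacing.copy(),
        origin=vol.origin.copy(),
    )
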