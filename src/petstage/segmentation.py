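"""Candidate uptake-region segmentation.

The central primitive is an incremental connected-component extraction with
per-region 45%-of-SUVmax thresholding: while any unassigned voxel exceeds
the SUV floor, the globally hottest unassigned voxel seeds a region grown at
45% of its SUV among unassigned voxels; the region is emitted and removed.
This deterministic max-first peeling yields pairwise-disjoint regions that
jointly cover every voxel above the floor.

Three entry points wrap the primitive for the annotation schemes used in
practice: fully automatic candidate generation (``incremental_connected_
components``), semi-automatic seeded annotation for low-burden subjects
(``segment_group_a``), and liver-referenced annotation with truncation to
the hottest 100 sites for high-burden subjects (``segment_group_b``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from petstage.errors import ConfigurationError
from petstage.io_volumes import PetCtVolume, Subject

logger = logging.getLogger(__name__)


@dataclass
class Finding:
    """One contiguous uptake region.

    The voxel set is stored as an (k, 3) integer index array together with
    the grid shape; ``suv_max`` is the PET maximum over the set and
    ``volume_ml`` the voxel count times the voxel volume.

    ``label_suspicious`` is one of ``"suspicious"``, ``"nonsuspicious"``,
    ``"unlabeled"``; ``provenance`` one of ``"expert"``,
    ``"auto_nonsuspicious"``, ``"candidate"``.
    """

    finding_id: str
    voxels: np.ndarray
    grid_shape: tuple[int, int, int]
    suv_max: float
    suv_max_voxel: tuple[int, int, int]
    volume_ml: float
    label_suspicious: str = "unlabeled"
    label_location: str = "unlabeled"
    provenance: str = "candidate"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.int32).reshape(-1, 3)
        if self.voxels.shape[0] == 0:
            raise ValueError("finding mask must be non-empty")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.shape[0])

    def to_mask(self) -> np.ndarray:
        mask = np.zeros(self.grid_shape, dtype=bool)
        mask[tuple(self.voxels.T)] = True
        return mask


@dataclass
class ReferenceRegion:
    """PERCIST-style normal-uptake reference: explicit mask or a sphere.

    The default sphere diameter is 30 mm, placed at a user-supplied centre
    (automatic liver localization is out of scope).
    """

    mask: np.ndarray | None = None
    center: tuple[int, int, int] | None = None
    radius_mm: float = 15.0

    def resolve(self, shape, spacing) -> np.ndarray:
        if self.mask is not None:
            return np.asarray(self.mask, dtype=bool)
        if self.center is None:
            raise ConfigurationError("reference region needs a mask or a center")
        grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
        d2 = sum(
            ((g - c) * s) ** 2 for g, c, s in zip(grids, self.center, spacing)
        )
        return d2 <= self.radius_mm**2


@dataclass
class SegmentationConfig:
    threshold_fraction: float = 0.45
    suv_floor: float = 1.0
    connectivity: int = 26
    max_regions: int | None = None
    liver_reference: ReferenceRegion | None = None

    def __post_init__(self) -> None:
        if not 0 < self.threshold_fraction < 1:
            raise ConfigurationError(
                f"threshold_fraction must be in (0, 1), got {self.threshold_fraction}"
            )
        if self.suv_floor < 0:
            raise ConfigurationError(f"suv_floor must be >= 0, got {self.suv_floor}")
        if self.connectivity not in (6, 26):
            raise ConfigurationError(
                f"connectivity must be 6 or 26, got {self.connectivity}"
            )


def _structure(connectivity: int) -> np.ndarray:
    return ndi.generate_binary_structure(3, 3 if connectivity == 26 else 1)


def _make_finding(
    comp: np.ndarray,
    pet: np.ndarray,
    spacing,
    finding_id: str,
    provenance: str = "candidate",
) -> Finding:
    voxels = np.argwhere(comp)
    flat = np.ravel_multi_index(tuple(voxels.T), pet.shape)
    vals = pet.ravel()[flat]
    top = int(np.argmax(vals))  # first occurrence = lowest linear index, argwhere is ordered
    voxel_volume_ml = float(np.prod(spacing)) / 1000.0
    return Finding(
        finding_id=finding_id,
        voxels=voxels,
        grid_shape=pet.shape,
        suv_max=float(vals[top]),
        suv_max_voxel=tuple(int(v) for v in voxels[top]),
        volume_ml=voxels.shape[0] * voxel_volume_ml,
        provenance=provenance,
    )


def incremental_connected_components(
    pet: np.ndarray,
    cfg: SegmentationConfig | None = None,
    spacing=(3.0, 3.0, 3.0),
    id_prefix: str = "cand",
) -> list[Finding]:
    """Extract candidate uptake regions by max-first peeling.

    While any unassigned voxel has SUV strictly above ``cfg.suv_floor``: the
    unassigned voxel ``p`` with globally maximal SUV (ties broken by lowest
    linear index) seeds a region; the connected component of unassigned
    voxels with SUV >= ``threshold_fraction * SUV(p)`` containing ``p`` is
    emitted and marked assigned.  Findings are returned sorted by SUVmax
    descending; ``cfg.max_regions`` truncates to the hottest regions.
    """
    cfg = cfg or SegmentationConfig()
    pet = np.asarray(pet, dtype=np.float32)
    struct = _structure(cfg.connectivity)
    work = pet.copy()
    work[work <= cfg.suv_floor] = -np.inf
    unassigned = np.ones(pet.shape, dtype=bool)
    findings: list[Finding] = []
    while True:
        p_flat = int(np.argmax(work))
        peak = work.ravel()[p_flat]
        if not np.isfinite(peak):
            break
        p = np.unravel_index(p_flat, pet.shape)
        t = cfg.threshold_fraction * float(peak)
        grow = (pet >= t) & unassigned
        labels, _ = ndi.label(grow, structure=struct)
        comp = labels == labels[p]
        findings.append(
            _make_finding(comp, pet, spacing, f"{id_prefix}{len(findings):04d}")
        )
        unassigned &= ~comp
        work[comp] = -np.inf
    findings.sort(key=lambda f: -f.suv_max)
    if cfg.max_regions is not None:
        findings = findings[: cfg.max_regions]
    return findings


def hill_climb(pet: np.ndarray, seed: tuple[int, int, int]) -> tuple[int, int, int]:
    """Ascend from ``seed`` to a local SUV maximum over the 26-neighbourhood.

    Ties are broken toward the lowest linear index, which also guarantees
    termination on plateaus.
    """
    pet = np.asarray(pet)
    shape = pet.shape
    cur = tuple(int(c) for c in seed)
    while True:
        lo = [max(0, c - 1) for c in cur]
        hi = [min(n, c + 2) for c, n in zip(cur, shape)]
        patch = pet[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        local = np.unravel_index(int(np.argmax(patch)), patch.shape)
        nxt = tuple(l + o for l, o in zip(lo, local))
        if pet[nxt] > pet[cur] or (
            pet[nxt] == pet[cur]
            and np.ravel_multi_index(nxt, shape) < np.ravel_multi_index(cur, shape)
        ):
            if nxt == cur:
                return cur
            cur = nxt
        else:
            return cur


def segment_group_a(
    pet: np.ndarray,
    seeds: list[tuple[int, int, int]],
    cfg: SegmentationConfig | None = None,
    spacing=(3.0, 3.0, 3.0),
    id_prefix: str = "exp",
) -> list[Finding]:
    """Semi-automatic seeded segmentation (low tumor-burden scheme).

    Each seed hill-climbs to its local SUV maximum; the region is grown at
    ``threshold_fraction`` of that maximum.  Seeds converging to the same
    SUVmax voxel are merged into one finding.  Seeds on zero uptake yield no
    finding (logged).
    """
    cfg = cfg or SegmentationConfig()
    pet = np.asarray(pet, dtype=np.float32)
    struct = _structure(cfg.connectivity)
    seen: dict[tuple[int, int, int], None] = {}
    findings: list[Finding] = []
    for seed in seeds:
        top = hill_climb(pet, seed)
        if pet[top] <= 0:
            logger.info("seed %s lies on zero uptake; skipped", seed)
            continue
        t = cfg.threshold_fraction * float(pet[top])
        labels, _ = ndi.label(pet >= t, structure=struct)
        comp = labels == labels[top]
        f = _make_finding(comp, pet, spacing, f"{id_prefix}{len(findings):04d}",
                          provenance="expert")
        if f.suv_max_voxel in seen:
            continue
        seen[f.suv_max_voxel] = None
        findings.append(f)
    return findings


def segment_group_b(
    pet: np.ndarray,
    cfg: SegmentationConfig,
    spacing=(3.0, 3.0, 3.0),
    id_prefix: str = "exp",
) -> list[Finding]:
    """Liver-referenced segmentation (high tumor-burden scheme).

    The SUV floor is the mean uptake over the PERCIST-style reference
    region; extraction is then identical to
    :func:`incremental_connected_components`, truncated to the
    ``max_regions`` (default 100) hottest sites.
    """
    if cfg.liver_reference is None:
        raise ConfigurationError("segment_group_b requires cfg.liver_reference")
    pet = np.asarray(pet, dtype=np.float32)
    ref = cfg.liver_reference.resolve(pet.shape, spacing)
    floor = float(pet[ref].mean()) if ref.any() else 0.0
    sub = SegmentationConfig(
        threshold_fraction=cfg.threshold_fraction,
        suv_floor=floor,
        connectivity=cfg.connectivity,
        max_regions=cfg.max_regions if cfg.max_regions is not None else 100,
    )
    out = incremental_connected_components(pet, sub, spacing, id_prefix=id_prefix)
    for f in out:
        f.provenance = "expert"
    return out


def generate_auto_nonsuspicious(
    subject: Subject,
    cfg: SegmentationConfig | None = None,
) -> list[Finding]:
    """Auto-generate nonsuspicious training regions (SUVmax > 1).

    Candidate regions from :func:`incremental_connected_components` at floor
    1.0 are discarded if their SUVmax voxel lies inside an expert-suspicious
    mask or their mask shares any voxel with one; the rest are labeled
    nonsuspicious.  Applied only for group-A subjects, or group-B subjects
    with at most nine expert-suspicious findings (where every suspicious
    site can be assumed annotated).
    """
    cfg = cfg or SegmentationConfig()
    base = SegmentationConfig(
        threshold_fraction=cfg.threshold_fraction,
        suv_floor=1.0,
        connectivity=cfg.connectivity,
    )
    suspicious = [f for f in subject.findings if f.label_suspicious == "suspicious"]
    if subject.group == "B" and len(suspicious) > 9:
        return []
    vol = subject.volume
    candidates = incremental_connected_components(
        vol.pet, base, vol.spacing, id_prefix=f"{subject.subject_id}-auto"
    )
    susp_mask = np.zeros(vol.shape, dtype=bool)
    for f in suspicious:
        susp_mask[tuple(f.voxels.T)] = True
    out = []
    for cand in candidates:
        if susp_mask[cand.suv_max_voxel]:
            continue
        if susp_mask[tuple(cand.voxels.T)].any():
            continue
        cand.label_suspicious = "nonsuspicious"
        cand.label_location = "unlabeled"
        cand.provenance = "auto_nonsuspicious"
        out.append(cand)
    return out


def findings_to_label_map(findings: list[Finding], shape) -> np.ndarray:
    """Integer label map (1-based, in list order); later findings win ties."""
    labels = np.zeros(shape, dtype=np.int16)
    for i, f in enumerate(findings, start=1):
        labels[tuple(f.voxels.T)] = i
    return labels


def findings_to_table(findings: list[Finding]):
    """Findings as a pandas DataFrame (CSV-ready)."""
    import pandas as pd

    rows = [
        {
            "finding_id": f.finding_id,
            "suv_max": f.suv_max,
            "x": f.suv_max_voxel[0],
            "y": f.suv_max_voxel[1],
            "z": f.suv_max_voxel[2],
            "n_voxels": f.n_voxels,
            "volume_ml": f.volume_ml,
            "label_suspicious": f.label_suspicious,
            "label_location": f.label_location,
            "provenance": f.provenance,
        }
        for f in findings
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "finding_id", "suv_max", "x", "y", "z", "n_voxels", "volume_ml",
            "label_suspicious", "label_location", "provenance",
        ],
    )
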