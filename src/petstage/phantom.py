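"""Synthetic dual-tracer PET/CT phantom subjects with ground truth.

Each phantom is a 64 x 64 x 160 grid at 3 mm (192 x 192 x 480 mm body
window, axes left-right / anterior-posterior / inferior-superior).  A soft
tissue body cylinder carries tracer-specific physiological organs painted
as ellipsoids (PSMA-like: liver, spleen, kidneys, bladder, salivary glands;
FDG-like: brain, cardiac, liver, bladder), a high-attenuation spine column,
and low-attenuation lungs.  Lesions are spheres (SUV uniform in 4-15,
radius 5-8 mm) placed in class-consistent zones:

* ``regional_node``  — pelvic ring around the bladder,
* ``extrapelvic_node`` — retroperitoneal midline zone,
* ``bone``           — on the spine column (high-HU context),
* ``other_organ``    — inside the right lung (low-HU context).

The PET volume is blurred with a Gaussian point-spread function (default
6 mm FWHM) and degraded with multiplicative Gaussian noise; expert-style
annotations are then re-derived with the same seeded 45%-of-SUVmax region
growing used for real annotation, so training labels share the geometry of
real ones.  Anatomical class is thus encoded by spatial zone and CT
context, which makes the location task learnable mainly from the CT
channel.

Organ SUV defaults are chosen for class separability, not as physiological
claims; everything is configurable.  The ground-truth stage always equals
the staging rules applied to the true lesion classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from petstage.errors import ConfigurationError, PetStageError
from petstage.io_volumes import PetCtVolume, Subject
from petstage.segmentation import Finding, SegmentationConfig, segment_group_a
from petstage.staging import LocationTaxonomy, StageResult, assign_stage

LESION_CLASSES = ("regional_node", "extrapelvic_node", "bone", "other_organ")


@dataclass
class OrganSpec:
    """One physiological structure: ellipsoid in voxel coordinates."""

    name: str
    center: tuple[float, float, float]
    radii: tuple[float, float, float]  # voxels
    suv: float
    hu: float
    annotate: bool = True  # emit an expert nonsuspicious finding


def psma_organs() -> list[OrganSpec]:
    return [
        OrganSpec("liver", (22, 30, 88), (11, 8, 9), suv=5.0, hu=60),
        OrganSpec("spleen", (45, 32, 90), (4, 4, 5), suv=6.0, hu=55),
        OrganSpec("kidney", (20, 40, 76), (4, 3, 6), suv=12.0, hu=45),
        OrganSpec("kidney", (44, 40, 76), (4, 3, 6), suv=12.0, hu=45),
        OrganSpec("bladder", (32, 34, 40), (5, 5, 5), suv=20.0, hu=20),
        OrganSpec("salivary", (26, 28, 138), (3, 3, 3), suv=8.0, hu=45),
        OrganSpec("salivary", (38, 28, 138), (3, 3, 3), suv=8.0, hu=45),
    ]


def fdg_organs() -> list[OrganSpec]:
    return [
        OrganSpec("brain", (32, 32, 148), (9, 8, 7), suv=8.0, hu=35),
        OrganSpec("cardiac", (26, 30, 112), (6, 5, 6), suv=6.0, hu=45),
        OrganSpec("liver", (22, 30, 88), (11, 8, 9), suv=2.5, hu=60),
        OrganSpec("bladder", (32, 34, 40), (5, 5, 5), suv=20.0, hu=20),
    ]


def phantom_location_classes() -> list[str]:
    return sorted(
        set(LESION_CLASSES)
        | {"liver", "spleen", "kidney", "bladder", "salivary", "brain", "cardiac"}
    )


def phantom_taxonomy() -> LocationTaxonomy:
    classes = phantom_location_classes()
    role_map = {c: (c if c in LESION_CLASSES else "physiological") for c in classes}
    return LocationTaxonomy(classes=classes, role_map=role_map)


@dataclass
class PhantomConfig:
    grid: tuple[int, int, int] = (64, 64, 160)
    spacing_mm: float = 3.0
    tracer: str = "PSMA"
    organ_set: list[OrganSpec] | None = None  # default: tracer-specific
    lesion_counts: dict[str, int] = field(default_factory=dict)
    lesion_suv_range: tuple[float, float] = (4.0, 15.0)
    lesion_radius_range_mm: tuple[float, float] = (5.0, 8.0)
    psf_fwhm_mm: float = 6.0
    noise_sigma_fraction: float = 0.05
    ct_noise_hu: float = 8.0
    background_suv: float = 0.3
    seed: int = 0
    max_retries: int = 20

    def __post_init__(self) -> None:
        if self.tracer not in ("PSMA", "FDG"):
            raise ConfigurationError(f"unknown tracer {self.tracer!r}")
        if self.lesion_suv_range[0] <= 1.0:
            raise ConfigurationError("lesion SUV range must stay above the 1.0 floor")
        for cls in self.lesion_counts:
            if cls not in LESION_CLASSES:
                raise ConfigurationError(f"unknown lesion class {cls!r}")


@dataclass
class GroundTruth:
    """True lesions and the stage they imply (consistent by construction)."""

    findings: list[Finding]
    stage: StageResult
    lesion_table: pd.DataFrame


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return d2 <= 1.0


_BODY_CENTER = (32.0, 32.0)
_BODY_RADII = (27.0, 21.0)
_SPINE_X = (30, 35)   # exclusive upper bounds
_SPINE_Y = (41, 46)
_SPINE_Z = (30, 130)
_BLADDER_CENTER = np.array([32.0, 34.0, 40.0])


def _draw_lesion_center(cls: str, rng: np.random.Generator) -> np.ndarray:
    if cls == "regional_node":
        for _ in range(200):
            x = rng.uniform(19, 45)
            y = rng.uniform(23, 39)
            z = rng.uniform(33, 49)
            p = np.array([x, y, z])
            if 11.0 <= np.linalg.norm(p - _BLADDER_CENTER) <= 15.0:
                return p
        raise PetStageError("could not place regional node")
    if cls == "extrapelvic_node":
        return np.array(
            [rng.uniform(28, 36), rng.uniform(28, 36), rng.uniform(58, 70)]
        )
    if cls == "bone":
        return np.array(
            [rng.uniform(31, 33), rng.uniform(42, 44), rng.uniform(36, 124)]
        )
    if cls == "other_organ":
        for _ in range(200):
            p = np.array(
                [rng.uniform(40, 48), rng.uniform(27, 33), rng.uniform(102, 122)]
            )
            # keep inside the right lung ellipsoid with margin
            d2 = (
                ((p[0] - 44) / 7) ** 2
                + ((p[1] - 30) / 5) ** 2
                + ((p[2] - 112) / 12) ** 2
            )
            if d2 <= 1.0:
                return p
        raise PetStageError("could not place lung lesion")
    raise ConfigurationError(f"unknown lesion class {cls!r}")


def _draw_lesions(cfg: PhantomConfig, rng: np.random.Generator) -> pd.DataFrame:
    for attempt in range(cfg.max_retries):
        rows = []
        ok = True
        for cls in LESION_CLASSES:
            for _ in range(cfg.lesion_counts.get(cls, 0)):
                radius = rng.uniform(*cfg.lesion_radius_range_mm) / cfg.spacing_mm
                # sequential rejection: keep blurred regions pairwise distinct
                for _try in range(300):
                    center = _draw_lesion_center(cls, rng)
                    if all(
                        np.linalg.norm(center - r["center"])
                        >= radius + r["radius_vox"] + 4.0
                        for r in rows
                    ):
                        break
                else:
                    ok = False
                    break
                rows.append({"cls": cls, "center": center,
                             "suv": rng.uniform(*cfg.lesion_suv_range),
                             "radius_vox": radius})
            if not ok:
                break
        if ok:
            return pd.DataFrame(rows, columns=["cls", "center", "suv", "radius_vox"])
    raise PetStageError(
        f"could not place {sum(cfg.lesion_counts.values())} lesions after "
        f"{cfg.max_retries} retries"
    )


def _paint_ct(cfg: PhantomConfig, organs: list[OrganSpec]) -> np.ndarray:
    shape = cfg.grid
    ct = np.full(shape, -1000.0, dtype=np.float64)
    xs, ys = np.ogrid[0 : shape[0], 0 : shape[1]]
    body2d = (
        ((xs - _BODY_CENTER[0]) / _BODY_RADII[0]) ** 2
        + ((ys - _BODY_CENTER[1]) / _BODY_RADII[1]) ** 2
    ) <= 1.0
    body = np.zeros(shape, dtype=bool)
    body[:, :, 4:156] = body2d[:, :, None]
    ct[body] = 40.0
    for c, r in (((20, 30, 112), (9, 7, 14)), ((44, 30, 112), (9, 7, 14))):
        ct[_ellipsoid_mask(shape, c, r)] = -700.0
    ct[_SPINE_X[0]:_SPINE_X[1], _SPINE_Y[0]:_SPINE_Y[1], _SPINE_Z[0]:_SPINE_Z[1]] = 700.0
    for organ in organs:
        ct[_ellipsoid_mask(shape, organ.center, organ.radii)] = organ.hu
    return ct


def generate_subject(cfg: PhantomConfig) -> tuple[Subject, GroundTruth]:
    """Generate one phantom subject with expert-style annotations.

    Deterministic given ``cfg.seed``.  Lesion geometry is drawn from a
    substream that does not depend on the tracer, so two configs differing
    only in ``tracer`` share identical lesion placements.
    """
    shape = cfg.grid
    organs = cfg.organ_set
    if organs is None:
        organs = psma_organs() if cfg.tracer == "PSMA" else fdg_organs()
    rng_lesion = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 11])
    rng_noise = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 13])

    lesions = _draw_lesions(cfg, rng_lesion)

    ct = _paint_ct(cfg, organs)
    body = ct > -500.0
    pet = np.zeros(shape, dtype=np.float64)
    pet[body] = cfg.background_suv
    for organ in organs:
        pet[_ellipsoid_mask(shape, organ.center, organ.radii)] = organ.suv
    for _, les in lesions.iterrows():
        mask = _ellipsoid_mask(shape, les["center"], [les["radius_vox"]] * 3)
        pet[mask] = np.maximum(pet[mask], les["suv"])

    sigma = cfg.psf_fwhm_mm / (2.3548 * cfg.spacing_mm)
    pet = gaussian_filter(pet, sigma)
    ct = gaussian_filter(ct, 0.4)
    pet = pet * (1.0 + cfg.noise_sigma_fraction * rng_noise.standard_normal(shape))
    np.clip(pet, 0.0, None, out=pet)
    ct = ct + cfg.ct_noise_hu * rng_noise.standard_normal(shape)

    vol = PetCtVolume(
        pet=pet.astype(np.float32),
        ct=ct.astype(np.float32),
        spacing=np.array([cfg.spacing_mm] * 3),
        origin=np.zeros(3),
    )

    seg_cfg = SegmentationConfig(threshold_fraction=0.45, suv_floor=1.0)
    # expert-style annotation: seeded 45% region growing at true peaks
    lesion_seeds = [tuple(int(round(v)) for v in c) for c in lesions["center"]]
    lesion_findings = segment_group_a(vol.pet, lesion_seeds, seg_cfg, vol.spacing,
                                      id_prefix="les")
    if len(lesion_findings) != len(lesions):
        # overlapping placements merged after blur; retry with a fresh draw
        if cfg.seed < 2**30:
            return generate_subject(replace(cfg, seed=cfg.seed + 2**30))
        raise PetStageError("lesions merged after blur; adjust lesion_counts")
    for f, (_, les) in zip(lesion_findings, lesions.iterrows()):
        f.label_suspicious = "suspicious"
        f.label_location = les["cls"]

    organ_seeds = [tuple(int(round(v)) for v in o.center) for o in organs if o.annotate]
    organ_findings = segment_group_a(vol.pet, organ_seeds, seg_cfg, vol.spacing,
                                     id_prefix="org")
    annotated = [o for o in organs if o.annotate]
    if len(organ_findings) == len(annotated):
        for f, o in zip(organ_findings, annotated):
            f.label_suspicious = "nonsuspicious"
            f.label_location = o.name
    else:  # an organ region swallowed another; keep unlabeled location
        for f in organ_findings:
            f.label_suspicious = "nonsuspicious"

    subject = Subject(
        subject_id=f"phantom-{cfg.tracer}-{cfg.seed}",
        tracer=cfg.tracer,
        volume=vol,
        findings=lesion_findings + organ_findings,
        group="A",
    )
    stage = assign_stage(list(lesions["cls"]), phantom_taxonomy())
    truth = GroundTruth(
        findings=lesion_findings,
        stage=stage,
        lesion_table=lesions.assign(
            x=[c[0] for c in lesions["center"]],
            y=[c[1] for c in lesions["center"]],
            z=[c[2] for c in lesions["center"]],
        ).drop(columns=["center"]),
    )
    return subject, truth


# -- cohorts ------------------------------------------------------------------

DEFAULT_STAGE_MIX: dict[tuple[str, str], float] = {
    ("N0", "M0"): 0.25,
    ("N1", "M0"): 0.15,
    ("N2", "M0"): 0.10,
    ("N0", "M1a"): 0.10,
    ("N1", "M1b_u"): 0.10,
    ("N0", "M1b_o"): 0.10,
    ("N1", "M1b_d"): 0.05,
    ("N2", "M1b_d"): 0.05,
    ("N0", "M1c"): 0.10,
}


def lesion_counts_for_stage(n_stage: str, m_stage: str,
                            rng: np.random.Generator) -> dict[str, int]:
    """Draw a lesion-count spec achieving the requested (miN, miM)."""
    counts = {c: 0 for c in LESION_CLASSES}
    if n_stage == "N1":
        counts["regional_node"] = 1
    elif n_stage == "N2":
        counts["regional_node"] = int(rng.integers(2, 4))
    elif n_stage != "N0":
        raise ConfigurationError(f"unknown N stage {n_stage!r}")
    if m_stage == "M1a":
        counts["extrapelvic_node"] = int(rng.integers(1, 3))
    elif m_stage == "M1b_u":
        counts["bone"] = 1
    elif m_stage == "M1b_o":
        counts["bone"] = int(rng.integers(2, 4))
    elif m_stage == "M1b_d":
        counts["bone"] = int(rng.integers(4, 6))
    elif m_stage == "M1c":
        counts["other_organ"] = int(rng.integers(1, 3))
    elif m_stage != "M0":
        raise ConfigurationError(f"unknown M stage {m_stage!r}")
    return counts


def draw_stage_targets(n: int, stage_mix: dict | None, seed: int) -> list[tuple[str, str]]:
    """Sample per-subject target stages from the mix (normalized)."""
    mix = stage_mix or DEFAULT_STAGE_MIX
    stages = list(mix)
    probs = np.asarray([mix[s] for s in stages], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 17])
    idx = rng.choice(len(stages), size=n, p=probs)
    return [stages[i] for i in idx]


def generate_cohort(
    n: int,
    stage_mix: dict | None = None,
    tracer: str = "PSMA",
    seed: int = 0,
    base_cfg: PhantomConfig | None = None,
    auto_nonsuspicious: bool = False,
) -> tuple[list[tuple[Subject, GroundTruth]], pd.DataFrame]:
    """Generate ``n`` phantom subjects with stages drawn from ``stage_mix``.

    Returns the subjects and a cohort metadata table (subject_id, tracer,
    true N/M stage) suitable for stratified splitting.  With
    ``auto_nonsuspicious=True`` every subject additionally carries the
    automatically generated nonsuspicious regions (SUVmax > 1) used for
    training.
    """
    from petstage.segmentation import generate_auto_nonsuspicious
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    targets = draw_stage_targets(n, stage_mix, seed)
    base = base_cfg or PhantomConfig(tracer=tracer)
    out = []
    meta = []
    for i, (n_stage, m_stage) in enumerate(targets):
        sub_seed = (seed * 100_003 + i * 37) & 0x3FFFFFFF
        rng = np.random.default_rng([sub_seed, 23])
        counts = lesion_counts_for_stage(n_stage, m_stage, rng)
        cfg = replace(base, tracer=tracer, lesion_counts=counts, seed=sub_seed)
        subject, truth = generate_subject(cfg)
        subject.subject_id = f"{tracer}-{seed}-{i:03d}"
        if auto_nonsuspicious:
            subject.findings.extend(generate_auto_nonsuspicious(subject))
        out.append((subject, truth))
        meta.append(
            {
                "subject_id": subject.subject_id,
                "tracer": tracer,
                "n_stage": truth.stage.n_stage,
                "m_stage": truth.stage.m_stage,
                "n_lesions": int(sum(counts.values())),
            }
        )
    return out, pd.DataFrame(meta)
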