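"""PROMISE miTNM N/M stage assignment from suspicious-region locations.

The anatomical classes the classifier emits are mapped to staging roles by
a configurable :class:`LocationTaxonomy`; each class has exactly one role:

* ``regional_node`` — pelvic lymph nodes (miN),
* ``extrapelvic_node`` — distant lymph nodes (miM1a),
* ``bone`` — skeletal metastases (miM1b, subdivided by lesion count),
* ``other_organ`` — visceral metastases (miM1c),
* ``local_prostate`` and ``physiological`` — contribute to neither N nor M.

Stage rules (counts of suspicious findings per role): N0 none / N1 single /
N2 multiple regional nodes; bone pattern M1b/u unifocal (1), M1b/o
oligometastatic (2-3), M1b/d disseminated (>= 4).  A subject receives the
single most advanced M category, precedence M1c > M1b > M1a > M0.  The
diffuse bone-marrow pattern is not modelled.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import yaml

from petstage.errors import ConfigurationError, UnknownClassError
from petstage.io_volumes import Subject
from petstage.mpr_features import extract_mpr
from petstage.segmentation import SegmentationConfig, incremental_connected_components

ROLES = (
    "regional_node",
    "extrapelvic_node",
    "bone",
    "other_organ",
    "local_prostate",
    "physiological",
)

N_STAGES = ("N0", "N1", "N2")
M_STAGES = ("M0", "M1a", "M1b_u", "M1b_o", "M1b_d", "M1c")


@dataclass
class LocationTaxonomy:
    """Anatomical class list with a role per class."""

    classes: list[str]
    role_map: dict[str, str]

    def __post_init__(self) -> None:
        for cls in self.classes:
            role = self.role_map.get(cls)
            if role is None:
                raise ConfigurationError(f"class {cls!r} has no role")
            if role not in ROLES:
                raise ConfigurationError(f"class {cls!r} has unknown role {role!r}")

    def role_of(self, cls: str) -> str:
        try:
            return self.role_map[cls]
        except KeyError:
            raise UnknownClassError(f"unknown anatomical class {cls!r}") from None

    @classmethod
    def from_yaml(cls, path) -> "LocationTaxonomy":
        data = yaml.safe_load(open(path))
        return cls(classes=list(data), role_map=dict(data))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.role_map, fh, sort_keys=False)


@dataclass
class StageResult:
    n_stage: str
    m_stage: str
    counts: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"n_stage": self.n_stage, "m_stage": self.m_stage,
                "counts": dict(self.counts)}


def assign_stage(suspicious_locations: list[str],
                 taxonomy: LocationTaxonomy) -> StageResult:
    """Map the locations of suspicious findings to (miN, miM).

    Order-independent; physiological and local-prostate classes are
    ignored.  Unknown class names raise :class:`UnknownClassError`.
    """
    roles = Counter(taxonomy.role_of(c) for c in suspicious_locations)
    r = roles["regional_node"]
    a = roles["extrapelvic_node"]
    b = roles["bone"]
    c = roles["other_organ"]

    n_stage = "N0" if r == 0 else ("N1" if r == 1 else "N2")
    if c >= 1:
        m_stage = "M1c"
    elif b >= 4:
        m_stage = "M1b_d"
    elif b >= 2:
        m_stage = "M1b_o"
    elif b == 1:
        m_stage = "M1b_u"
    elif a >= 1:
        m_stage = "M1a"
    else:
        m_stage = "M0"
    return StageResult(n_stage=n_stage, m_stage=m_stage, counts=dict(roles))


def stage_subject(
    model,
    subject: Subject,
    taxonomy: LocationTaxonomy,
    seg_cfg: SegmentationConfig | None = None,
    threshold: float = 0.5,
    predict_fn=None,
) -> StageResult:
    """Fully automatic staging of one subject.

    Pipeline: candidate extraction at SUV floor 1.0 -> MPR stack per
    candidate -> network classification -> locations of candidates with
    ``p_suspicious >= threshold`` -> :func:`assign_stage`.

    ``predict_fn(finding) -> (p_suspicious, location_class or None)`` may
    replace the network (e.g. a ground-truth oracle in tests).
    """
    from petstage.cnn_model import TRACER_BIT

    seg_cfg = seg_cfg or SegmentationConfig(suv_floor=1.0)
    vol = subject.volume
    candidates = incremental_connected_components(vol.pet, seg_cfg, vol.spacing)
    locations: list[str] = []
    if predict_fn is not None:
        for cand in candidates:
            p, loc = predict_fn(cand)
            if p >= threshold and loc is not None:
                locations.append(loc)
        return assign_stage(locations, taxonomy)

    if model.location_classes is None:
        raise ConfigurationError("model carries no location-class list")
    if candidates:
        x = np.stack(
            [extract_mpr(vol, c.suv_max_voxel).as_network_input() for c in candidates]
        )
        t = (
            np.full(len(candidates), TRACER_BIT[subject.tracer])
            if model.cfg.dual_tracer
            else None
        )
        p_susp, probs = model.predict_batch(x, t)
        for i in range(len(candidates)):
            if p_susp[i] >= threshold:
                locations.append(model.location_classes[int(np.argmax(probs[i]))])
    return assign_stage(locations, taxonomy)
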