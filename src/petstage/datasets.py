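"""Bundled reference data: a published clinical reading study (52 subjects).

A whole-body ^68Ga-PSMA-11 PET/CT reading study compared PROMISE miTNM
N/M stages assigned from automated network annotations against stages from
expert annotations on a 52-subject hold-out test set, alongside pooled
lesion-detection counts.  The confusion matrices and pooled counts are
reproduced here as worked-example inputs for the evaluation operations
(percent agreement, recall, positive predictive value).

Rows are the expert (annotation) stage, columns the predicted stage.
"""

from __future__ import annotations

import numpy as np

from petstage.evaluation import ConfusionMatrix

N_STAGE_LABELS = ("miN0", "miN1", "miN2")
M_STAGE_LABELS = ("miM0", "miM1a", "miM1b/u", "miM1b/o", "miM1b/d", "miM1c")


def clinical_n_stage_confusion() -> ConfusionMatrix:
    """N-stage confusion matrix of the 52-subject clinical test set."""
    counts = np.array(
        [
            [14, 7, 1],
            [2, 11, 4],
            [0, 3, 10],
        ]
    )
    return ConfusionMatrix(labels=list(N_STAGE_LABELS), counts=counts)


def clinical_m_stage_confusion() -> ConfusionMatrix:
    """M-stage confusion matrix of the 52-subject clinical test set."""
    counts = np.array(
        [
            [8, 5, 4, 0, 0, 0],
            [2, 6, 1, 0, 0, 0],
            [1, 0, 7, 4, 0, 1],
            [0, 0, 0, 3, 1, 0],
            [0, 0, 0, 1, 6, 0],
            [0, 0, 0, 0, 0, 2],
        ]
    )
    return ConfusionMatrix(labels=list(M_STAGE_LABELS), counts=counts)


def clinical_detection_counts() -> dict[str, int]:
    """Pooled detection counts (suspicious-lesion identification)."""
    return {"tp": 159, "fp": 79, "fn": 37}


# merge maps for the coarser agreement questions
N_ANY_INVOLVEMENT_MERGE = {"miN1": "miN1/2", "miN2": "miN1/2"}
M_BONE_PATTERN_MERGE = {"miM1b/u": "miM1b", "miM1b/o": "miM1b", "miM1b/d": "miM1b"}
M_ANY_METASTASIS_MERGE = {
    "miM1a": "miM1",
    "miM1b/u": "miM1",
    "miM1b/o": "miM1",
    "miM1b/d": "miM1",
    "miM1c": "miM1",
}
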