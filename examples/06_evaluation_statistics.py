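"""The evaluation toolbox on the bundled clinical worked examples.

A published 52-subject reading study compared automatic and expert miTNM
stages; its confusion matrices and pooled detection counts ship with the
package.  Percent agreement, recall and PPV recompute the printed figures
exactly; a subject-level bootstrap illustrates the confidence-interval
machinery on synthetic per-subject data.
"""

import numpy as np

from petstage import datasets
from petstage.evaluation import (
    bootstrap_ci,
    detection_counts_to_percents,
    paired_z_test,
    stage_agreement,
)

n_cm = datasets.clinical_n_stage_confusion()
m_cm = datasets.clinical_m_stage_confusion()
print("N-stage agreement:", stage_agreement(n_cm)[0], "%")
print("  N0 vs N1/N2    :",
      stage_agreement(n_cm, datasets.N_ANY_INVOLVEMENT_MERGE)[0], "%")
print("M-stage agreement:", stage_agreement(m_cm)[0], "%")
print("  bone merged    :",
      stage_agreement(m_cm, datasets.M_BONE_PATTERN_MERGE)[0], "%")
print("  M0 vs M1       :",
      stage_agreement(m_cm, datasets.M_ANY_METASTASIS_MERGE)[0], "%")

recall, ppv = detection_counts_to_percents(**datasets.clinical_detection_counts())
print(f"detection recall {recall:.1f}%  PPV {ppv:.1f}%  (TP 159, FP 79, FN 37)")

# subject-level percentile bootstrap (2000 resamples is the standard setting;
# 500 here for a quick demo) on a synthetic per-subject accuracy
rng = np.random.default_rng(0)
per_subject = list(rng.normal(80.0, 8.0, 40))
lo, hi, reps = bootstrap_ci(lambda s: float(np.mean(s)), per_subject,
                            b=500, seed=1)
print(f"bootstrap 95% CI for a mean per-subject accuracy of "
      f"{np.mean(per_subject):.1f}: ({lo:.1f}, {hi:.1f})")

# paired z-test on matched replicate vectors (scheme A vs scheme B)
reps_b = reps - rng.normal(1.0, 2.0, len(reps))
z, p_raw, p_bonf = paired_z_test(reps, reps_b, n_comparisons=5)
print(f"paired z-test A vs B: z={z:.2f}, p={p_raw:.4f}, "
      f"Bonferroni (5 comparisons) p={p_bonf:.4f}")
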