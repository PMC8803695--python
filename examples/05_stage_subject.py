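"""Automatic PROMISE miTNM N/M staging of one subject.

The pipeline segments all regions above SUV 1, classifies each candidate,
and maps the anatomical locations of suspicious-classified regions to an
N category (regional nodes: 0 / 1 / many) and an M category (extrapelvic
nodes M1a; bone M1b unifocal/oligo/disseminated by count; other organs
M1c).  Here the classifier is replaced by a ground-truth oracle to show
the staging layer in isolation.
"""

from petstage.phantom import PhantomConfig, generate_subject, phantom_taxonomy
from petstage.staging import assign_stage, stage_subject

subject, truth = generate_subject(
    PhantomConfig(tracer="PSMA",
                  lesion_counts={"regional_node": 1, "bone": 3}, seed=13)
)
print(f"true stage: {truth.stage.n_stage} {truth.stage.m_stage} "
      "(1 pelvic node, 3 bone lesions -> N1 + oligometastatic bone)")

lesions = {tuple(f.suv_max_voxel): f.label_location for f in truth.findings}
result = stage_subject(
    None, subject, phantom_taxonomy(),
    predict_fn=lambda c: (1.0, lesions[tuple(c.suv_max_voxel)])
    if tuple(c.suv_max_voxel) in lesions else (0.0, None),
)
print(f"pipeline stage: {result.n_stage} {result.m_stage}  "
      f"(role counts {result.counts})")

# the rules alone, on location labels:
demo = assign_stage(["bone"] * 5 + ["extrapelvic_node"], phantom_taxonomy())
print(f"5 bone + 1 distant node -> {demo.n_stage} {demo.m_stage} "
      "(>= 4 bone lesions dominate: disseminated M1b_d)")
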