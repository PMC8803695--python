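"""Generate a synthetic PSMA-like PET/CT subject with known ground truth.

The phantom paints tracer-specific physiological organs and inserts
spherical lesions in class-consistent zones (pelvic nodes, retroperitoneal
nodes, spine, lung), then applies PET blur and noise.  Expert-style
annotations are re-derived with 45%-of-SUVmax region growing, so the labels
have the same geometry a human reader would produce.
"""

from petstage.phantom import PhantomConfig, generate_subject

cfg = PhantomConfig(
    tracer="PSMA",
    lesion_counts={"regional_node": 1, "bone": 2},
    seed=7,
)
subject, truth = generate_subject(cfg)

print(f"subject {subject.subject_id}: grid {subject.volume.shape}, "
      f"3 mm isotropic, tracer {subject.tracer}")
print(f"true stage: {truth.stage.n_stage} {truth.stage.m_stage} "
      "(one pelvic node -> N1; two bone lesions -> oligometastatic M1b_o)")
print(f"{len(subject.findings)} annotated findings:")
for f in subject.findings:
    print(f"  {f.finding_id:10s} {f.label_suspicious:13s} {f.label_location:16s}"
          f" SUVmax {f.suv_max:5.1f}  {f.volume_ml:5.2f} ml")
# SUVmax is the hottest voxel of each region; volumes follow from the
# 45% threshold, so hotter lesions segment slightly smaller than painted.
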