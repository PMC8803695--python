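"""The network input: thirteen two-channel coronal reformations.

Planes are sampled at fixed anterior-posterior offsets (-144 .. +144 mm)
around a region's SUVmax position, 192 mm x 192 mm each at the 3 mm grid;
PET is windowed to [0, 15] SUV and CT to [-300, 300] HU, both scaled to
[0, 1].  Affine augmentation re-extracts the stack under a random rotation
(±17.2° per axis) and isotropic scaling (0.8-1.2) about the centre.
"""

import numpy as np

from petstage.mpr_features import MPR_OFFSETS_MM, augment_affine, extract_mpr
from petstage.phantom import PhantomConfig, generate_subject

subject, truth = generate_subject(
    PhantomConfig(tracer="PSMA", lesion_counts={"bone": 1}, seed=5)
)
lesion = truth.findings[0]
stack = extract_mpr(subject.volume, lesion.suv_max_voxel)

print(f"stack shape {stack.planes.shape} (plane, PET/CT, 64 x 64)")
print(f"offsets (mm): {MPR_OFFSETS_MM}")
centre_pet = stack.planes[6, 0, 32, 32]
print(f"centre PET sample {centre_pet:.3f} = SUVmax {lesion.suv_max:.1f} / 15 "
      "(clamped-window normalization)")
print(f"value range [{stack.planes.min():.3f}, {stack.planes.max():.3f}] — "
      "always inside [0, 1]")

aug = augment_affine(subject.volume, lesion.suv_max_voxel, rng_seed=11)
diff = np.abs(aug.planes - stack.planes).max()
print(f"augmented stack differs by up to {diff:.3f} off-centre, but the "
      f"centre sample moves only {abs(aug.planes[6,0,32,32]-centre_pet):.4f} "
      "(rotations and scaling fix the centre point)")
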