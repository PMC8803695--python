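# Methods

## Scope and model

`petstage` automates the reading of whole-body PET/CT for prostate-cancer
staging: segment every site of elevated tracer uptake, classify each site
as suspicious or nonsuspicious for cancer and assign it an anatomical
location, then map the suspicious locations to PROMISE miTNM miN/miM
categories. The design assumption throughout is that a *region of
interest*, not a whole scan, is the unit of learning: scans with only
partial expert annotation still contribute training regions, and the
number of regions per scan (tens to hundreds) provides the sample size.

## Segmentation

The core primitive is a deterministic max-first peeling. Let F be the SUV
floor (1.0 for automatic candidates) and f the threshold fraction (0.45).
While any unassigned voxel has SUV > F: take the unassigned voxel p of
globally maximal SUV (ties broken toward the lowest linear index), grow
the 26-connected component of unassigned voxels with SUV ≥ f·SUV(p)
containing p, emit it, mark it assigned. Consequences worth knowing:

* Emitted regions are pairwise disjoint, and every voxel above the floor
  is assigned to exactly one region (when no truncation is applied).
* A bright object produces its 45% "core" region *and* one or more
  sub-threshold **rim fragments** ("shells") between the floor and the
  45% level, emitted as separate low-SUV regions. This is inherent to
  per-region thresholds with a global floor and matters for staging (see
  Limitations).
* Connectivity is 26 by default (6 available); interpolation plays no
  role — the procedure operates on the voxel grid.

Two annotation schemes wrap the primitive: seed-click segmentation
(hill-climb each seed to its local maximum over the 26-neighbourhood,
grow at 45% of that maximum, merge seeds that reach the same SUVmax
voxel), and a liver-referenced scheme whose floor is the mean SUV over a
PERCIST-style reference region (user-supplied mask or 30 mm sphere),
truncated to the 100 hottest sites. Auto-generated nonsuspicious training
regions are candidates at floor 1.0 that neither contain an
expert-suspicious SUVmax voxel nor share any voxel with an
expert-suspicious mask; they carry no anatomical label and their location
loss is masked.

## Geometry and features

Volumes are stored on LPS patient axes, resampled to 3 mm isotropic with
trilinear interpolation (nearest-neighbour for label maps); negative SUV
reconstruction noise is clamped to zero at load. The network input for
one region is a stack of 13 coronal planes at anterior-posterior offsets
(−144, −96, −48, −24, −12, −6, 0, 6, 12, 24, 48, 96, 144) mm from the
region's SUVmax voxel, each 64 × 64 samples at the 3 mm grid (192 mm
square), two channels: PET clamped to [0, 15] SUV then divided by 15, CT
clamped to [−300, 300] HU then mapped affinely to [0, 1]. Samples outside
the volume take the window minimum, i.e. 0 after normalization.
Windowed intensities are normalized to [0, 1] (exposed in the module
constants) — raw clamped values would only rescale first-layer weights.

Augmentation draws an isotropic scale s ~ U(0.8, 1.2) and three rotation
angles ~ U(−17.2°, 17.2°), applied extrinsically about the patient axes
in x → y → z order, about the centre position, and re-extracts the stack;
with the ranges collapsed to identity the output equals plain extraction
bit-exactly (same code path, exact identity matrix). The centre sample is
a fixed point of the transform. Sampling uses a shared-weight trilinear
gather over both channels with the volume padded by the fill value, which
matches constant-boundary `map_coordinates` output exactly (verified in
tests) at about half the cost.

## Network

A shared convolutional trunk (default four 3×3 conv + ReLU + 2×2 max-pool
blocks, base 16 filters doubling per block, capped at 128) feeds two
fully connected heads: the suspicious head (128-wide FC + ReLU → 1 sigmoid
output) and the location head (128-wide FC + ReLU → softmax). In the
dual-tracer variant a single binary input (0 = PSMA-like, 1 = FDG-like)
is concatenated to the input of the suspicious head's first FC layer
only. Two properties follow structurally and are asserted in tests: the
gradient of the location loss with respect to the tracer-bit weights is
identically zero, and flipping the bit changes only p(suspicious).

The implementation is plain numpy with explicit backward passes (verified
against finite differences to ~1e-6 relative error) and an Adam
optimizer. An optional parameter-free 2×2 **max**-pool in front of the
trunk (`pool_first`) quarters the cost of toy models; max rather than
average pooling because averaging provably destroys the
"centre-is-the-local-maximum" cue that separates lesion-centred stacks
from rim fragments of a hotter neighbour.

Losses: binary cross-entropy on the suspicious head (optional
positive-class weight against the residual ~15:1 imbalance that survives
balanced sampling) plus categorical cross-entropy on the location head,
masked for regions without an anatomical label, summed 1:1 by default.
Exact layer sizes are configuration, not contract; the architectural
claims this package fixes are the multi-task split and the tracer-bit
placement.

## Training strategies

I sequential sampling of every training finding; II balanced sampling —
per subject and epoch at most 32 nonsuspicious and 32 suspicious findings
plus a top-up of at most 4 findings per labeled anatomical class; III = II
plus affine augmentation of every drawn example; IV = III on the FDG
dataset with a single 90/10 subject-level split; V = fine-tune the IV
checkpoint on PSMA data with III (all weights updated, no freezing);
VI = III over both tracers' subjects with the dual-tracer model, the bit
taken from each subject's tracer tag (an ablation flag can force it
constant). The two balanced-sampling caps interact: the per-class top-up
never breaches the 32/32 binary caps, so no cap is ever exceeded — the
union is taken subject to the binary budgets. Optimizer defaults
(Adam, lr 1e-3, batch 32, 50 epochs) are configuration; the packaged
benchmark uses 10 epochs at its cohort size. Cross-validation is
subject-level and stratified (by any-suspicious flag, or a supplied
per-subject stratum such as true stage), pooling predictions across folds.

## Staging rules

With r / a / b / c the counts of suspicious findings in regional-node /
extrapelvic-node / bone / other-organ roles: miN = N0, N1, N2 for r = 0,
1, ≥2; bone pattern M1b_u (b = 1), M1b_o (2 ≤ b ≤ 3), M1b_d (b ≥ 4);
miM = the most advanced applicable category, precedence
M1c > M1b_* > M1a > M0. Physiological and local-prostate classes
contribute to neither. One M category per subject; the diffuse
bone-marrow pattern is not modelled. The class → role map is
configuration (YAML), since anatomical class lists vary by site.

## Evaluation

Average precision is the area under the step-wise precision-recall curve,
tied scores grouped into one threshold, no interpolation. Detection
matching: a suspicious-classified candidate matches an expert-suspicious
finding if its SUVmax voxel lies inside the expert mask (default) or if
the masks share any voxel (configurable); TP counts matched expert
findings (a double match counts once), FP suspicious candidates matching
nothing, FN unmatched expert findings, so TP + FN equals the number of
expert positives. Per-subject recall for subjects without expert
positives is 100 by convention only when the subject also has no
suspicious predictions, otherwise undefined and excluded from the
summary. CIs are subject-level percentile bootstrap (default B = 2000;
replicates on which the metric is undefined are redrawn and counted).
The paired z-test uses z = mean(d)/sd(d) on matched replicate vectors,
two-sided normal p, Bonferroni multiplied and capped at 1; sd = 0
degenerates to p = 1 (mean 0) or p = 0 (flagged). Agreement is
100·trace/total of a confusion matrix after optional category merging,
reported rounded to integer with the unrounded value retained.

## Phantom generator

Each phantom is a 64 × 64 × 160 grid at 3 mm: a soft-tissue body cylinder
(40 HU), two low-attenuation lungs (−700 HU), a high-attenuation spine
column (700 HU), and tracer-specific physiological organs painted as
ellipsoids — PSMA-like: liver 5, spleen 6, kidneys 12, bladder 20,
salivary 8 SUV; FDG-like: brain 8, cardiac 6, liver 2.5, bladder 20.
Lesions are spheres (SUV ~ U(4, 15), radius ~ U(5, 8) mm) placed with
rejection sampling in class-consistent zones: a pelvic ring around the
bladder (regional nodes), a retroperitoneal midline zone (extrapelvic
nodes), the spine column (bone; high-HU context), and the right lung
(other organs; low-HU context). PET is blurred with a 6 mm FWHM Gaussian
point-spread function and degraded with 5% multiplicative Gaussian noise
(CT: 8 HU additive). Organ SUVs are chosen for class separability, not as
physiological claims. Expert-style annotations are re-derived with the
same seed-click 45% region growing used for real annotation, so training
labels share the geometry of real ones; the ground-truth stage always
equals the staging rules applied to the true lesion classes. Lesion
geometry is drawn from a tracer-independent substream, so two tracers at
the same seed share lesions but differ in physiology. Cohorts draw each
subject's target stage from a configurable mix and derive a lesion-count
spec achieving it.

What the phantom does *not* emulate: anatomical realism (organs are
ellipsoids), attenuation/scatter physics, scanner-specific noise texture,
respiratory motion, lesion-shape variability, and reader disagreement.
Passing tests on it demonstrate that the pipeline's machinery —
segmentation, feature geometry, learning, staging arithmetic, statistics
— is correct and learnable at desk scale; they say nothing quantitative
about clinical images.

## Packaged benchmark and its interpretation

`petstage.benchmark.run_phantom_benchmark` generates 60 training and 20
validation subjects, trains the compact model (16 base filters, front
max-pool, 128-wide heads, strategy III, 10 epochs, suspicious-head
positive weight 4) and reports: pooled AP and location accuracy on
held-out expert-labeled findings; model-based N/M stage agreement and
exact (miN, miM) recovery from the fully automatic pipeline; and the same
exact recovery with ground-truth classification injected into the same
candidate pipeline, which isolates candidate generation and the staging
rules from classifier errors. A three-seed run completes in roughly ten
CPU-minutes.

At this scale the classifier separates lesions from physiological organs
essentially perfectly (AP ≈ 100) but cannot reliably reject the rim
fragments the peeling emits around each lesion: a rim-centred feature
stack differs from a lesion-centred one only in whether the centre sample
is the local maximum, and after blur, noise and augmentation the two
output distributions overlap at this model scale. Each suspicious rim
inflates a role count by one, so model-based *exact* stage recovery stays
well below the oracle's — the same N/M disagreement pattern the agreement
statistics are designed to quantify — while the oracle-classification
recovery shows the candidate and staging layers themselves are exact. Both numbers are reported; the benchmark's
passing bar is pooled AP ≥ 90 together with oracle-classification exact
recovery ≥ 80%.

## Numerical choices and degenerate inputs

* Ties in peak selection, hill-climbing and argmax location predictions
  break toward the lowest (linear) index — determinism everywhere.
* All-zero volumes segment to an empty finding list; seeds on zero uptake
  are skipped with a log message.
* Resampling clamps sample coordinates to the source grid (no border
  bleed); single-slice axes are rejected by name.
* Sigmoid logits are clipped at ±30; softmax is max-shifted; bootstrap
  seeds and every derived generator seed stay below 2^31.
* Bit-exact reproducibility: same seed ⇒ identical phantom volumes,
  epoch selections, augmentations, initial weights and training
  trajectories (single-threaded numpy arithmetic).

## Known limitations

* The rim-fragment ambiguity above is the dominant error source of the
  fully automatic staging at phantom scale; candidate post-merging could
  remove it but is deliberately out of scope (the staging contract counts
  classified candidates as they come).
* The liver reference region must be supplied (mask or sphere centre);
  automatic liver localization is out of scope, as are DICOM ingestion,
  SUV calibration, miT staging and the diffuse bone-marrow pattern.
* The numpy network is CPU-bound and meant for desk-scale experiments,
  not clinical-scale training.
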