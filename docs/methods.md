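# Methods

## Problem and approach

Quantifying tongue-muscle atrophy (a hallmark of bulbar involvement in motor
neuron disease) requires segmenting the tongue in routine T1-weighted head
MRI and measuring the segmented volume. `tongueseg` implements a *triplanar
consensus* approach: one shared 2-D U-Net is trained on axial, sagittal and
coronal slices pooled across subjects, applied slice-wise along each of the
three orthogonal orientations at inference time, and the three per-voxel
predictions are fused into a single binary mask. Compared with a 3-D network
or three orientation-specific 2-D networks, a single triplanar network shares
features across planes and needs only cubic resampled inputs so that slices
from all orientations have identical dimensions.

## Pipeline

1. **Resampling.** Each volume is tri-linearly resampled to a cubic working
   grid (canonically 256³ voxels at 1.0 mm isotropic). Masks are
   interpolated as float fields and re-binarized at 0.5, with ties counted
   as foreground.
2. **Reorientation.** An integer-voxel translation puts an anatomical
   landmark at the matrix center, and grid axes are permuted/flipped into
   the canonical (AP, LR, IS) order. The landmark is supplied externally: a
   stored palatal-tip coordinate for clinical data, the exact mask centroid
   for phantoms. No automatic landmark detector is attempted.
3. **Cohort z-scoring.** For each subject, the mean intensity over a
   tongue-centered ROI (canonically 128³ voxels at 1 mm — half the working
   extent per axis) is computed; the cohort mean `M` and the sample (n−1)
   standard deviation `S` of those per-subject means normalize every voxel
   of every subject identically as `(x − M)/S`. An alternative per-subject
   reading (each subject scaled by its own ROI mean/SD) is available as
   `znormalize_per_subject` but is off the default path. Normalized
   intensities are carried in float64 so the self-normalization identities
   (cohort mean/SD of ROI means exactly 0/1) hold to machine precision;
   values are narrowed to float32 at the network boundary.
4. **Segmentation grid.** The central region covering half the working
   extent is cropped and upsampled ×2 (canonically the central 128 mm cube
   to 256³ at 0.5 mm). The inverse mapping (`from_segmentation_grid`)
   re-embeds predictions in working-grid coordinates.

## Network

A same-padded U-Net with encoder channel plan (32, 64, 128, 256, 512) by
default. Per encoder level: two 3×3 conv + ReLU, dropout, 2×2 max-pool (no
pool at the deepest level). Per decoder level: nearest-neighbour ×2
upsampling followed by a 2×2 convolution, concatenation with the matching
encoder output, two 3×3 conv + ReLU. Head: 1×1 convolution to two classes
with per-pixel softmax. Design choices where the architecture admits
variants:

* *Same padding* (the classic U-Net is valid-padded) — slice-wise volume
  reassembly requires output size = input size.
* *Dropout placement*: once per encoder block, after the conv pair; rate
  defaults to 0.5 (0.2 in the desk-scale configuration below), configurable.
* *No batch normalization.*
* *Upsampling*: nearest-neighbour ×2 followed by a 2×2 convolution by
  default; a stride-2 2×2 transposed convolution is available via
  `up_mode="transposed"`.
* *Zero-initialized head*: the final 1×1 convolution starts at zero so an
  untrained network outputs exactly uniform class probabilities; all other
  weights are seeded He-normal.
* *Two-channel softmax* rather than single-channel sigmoid, matching the
  categorical cross-entropy loss.

The network, its backpropagation and the Adam optimizer (β₁ = 0.9,
β₂ = 0.999, ε = 1e−7) are implemented directly on numpy; convolutions are
evaluated as sums of shifted BLAS matrix products in float32. Gradients are
validated against central finite differences in the test suite. Runs are
bit-reproducible for a fixed seed in single-threaded BLAS mode.

## Training

Slices from all three orientations of all training subjects are pooled;
slices without foreground are kept (the tongue occupies a minority of
slices) and no class reweighting is applied, consistent with the plain
categorical cross-entropy. Fivefold cross-validation splits at the
*subject* level (every slice of a subject stays on one side), preventing
leakage; each fold trains with Adam (default learning rate 1e−4, batch 16,
up to 50 epochs) and early stopping on validation loss with patience 10,
restoring the best-epoch weights. The fold's validation mean IoU (two-class
mean, pooled over validation pixels) becomes its fixed ensembling weight
`w_f`. The two-class reading of "mean IoU" was chosen over foreground-only
IoU; both are near-monotonically related here, and the weight only sets the
relative influence of folds.

## Inference and consensus

For one orientation, every slice is predicted by all five fold models and
the foreground probabilities are combined voxel-wise as
`s = Σ w_f p_f / Σ w_f`. The three orientation grids are fused by one of:

* **softmax** — equal-weight average of the three probability grids,
  thresholded at `t`;
* **union / majority / unanimous** — each orientation thresholded first,
  then a voxel is kept with ≥1 / ≥2 / =3 positive votes.

The hard threshold defaults to `t = 0.5`; a voxel exactly at `t` counts as
positive (equivalent to 2-class argmax with background winning ties only
above threshold). Fold ensembling always happens within an orientation
before any cross-orientation merge. With hard inputs and equal weights,
softmax averaging and majority voting coincide (verified exhaustively over
all 8 vote patterns); with soft inputs they can differ — e.g. probabilities
(0.9, 0.3, 0.3) average to 0.5 (positive) while the hardened votes are
1-of-3 (negative). No connected-component or morphological post-processing
is applied.

## Evaluation and statistics

Confusion counts are taken over the full segmentation grid (so
TP+TN+FP+FN equals the grid size). Precision, recall, Dice (= F1) and
foreground IoU follow the usual definitions; undefined ratios (empty masks)
are reported as missing rather than 0 so cohort means stay honest. Summary
tables average *per-subject* metrics (mean ± sd), not metrics of pooled
counts. Volume is the positive-voxel count times the voxel volume, reported
in cm³ (a healthy adult tongue is roughly 90–110 cm³).

Volume comparisons are gated by Shapiro–Wilk normality at α = 0.05:
predicted-vs-truth uses a paired Student's t test when the paired
differences pass, otherwise a Wilcoxon signed-rank test (a documented
extension of the parametric-only path); between-group comparisons use the
pooled-variance unpaired t test when both groups pass, otherwise the
two-sided Mann–Whitney U. Zero-variance differences are reported as
degenerate rather than assigned a fabricated p-value. All tests are
delegated to scipy and cross-checked against R's implementations to 1e−8 in
the acceptance suite.

## Synthetic phantoms

No public tongue-MRI dataset with masks exists, so the toolkit ships a
phantom generator that emulates the statistical structure of the intended
data:

* a bright "tongue": an ellipsoid with default semi-axes
  (35.75, 23.75, 30.0) mm along (AP, LR, IS) — matching typical organ
  extents of ~143 coronal / 95 sagittal / 120 axial slices at 0.5 mm and a
  volume of ≈ 106.7 cm³ — smoothly deformed by a seeded degree-2
  spherical-harmonic perturbation of the boundary radius (default
  amplitude 0.05) to mimic inter-subject shape variation;
* 2–4 ellipsoidal *distractor* blobs of near-tongue intensity placed
  adjacent to (never overlapping) the tongue, reproducing the
  hard-to-separate lip/soft-palate voxels;
* a ~1-voxel Gaussian blur of the tissue map (partial-volume-like soft
  edges) plus additive Gaussian noise (default σ = 10 against a
  tongue/background contrast of 100/20, arbitrary units);
* atrophy modelled as a multiplicative factor on all semi-axes
  (`volume_scale`), so true volume scales with its cube.

Cohorts draw per-subject `volume_scale` from per-group normal
distributions. The default two-arm design mirrors a bulbar-onset atrophy
study: controls at 106 ± 8 cm³ and an atrophic arm at 91 ± 16 cm³ (≈14%
smaller mean), n = 19 per arm; since volume ∝ scale³, scale SDs are set to
one third of the relative volume SDs. Per-subject seeds depend only on the
master seed and the subject index, so two arms with identical distributions
yield pairwise-matched subjects.

**What the phantoms do not model**: MRI physics (bias fields, Rician noise,
motion artifacts), full head anatomy, and tongue-motion blur. Passing tests
therefore demonstrate the correctness and internal consistency of the
pipeline — preprocessing conservation, fusion logic, statistics, and the
learnability of a bright deformable organ among distractors — not clinical
segmentation accuracy on real MPRAGE data.

## Scaled-down study configuration

The full-scale setup (256³ at 0.5 mm, 32–512 channels, 50 epochs) runs
through the same code path but is not exercised by the test suite. The
default desk-scale study keeps the physical geometry (128 mm field of view,
identical tongue sizes) at 2 mm resolution:

* phantoms and grids: 64³ at 2 mm; normalization ROI 32³ at 2 mm;
* network: channels (8, 16, 32), input 64, dropout 0.2 — 29,330 parameters;
* training: 20-subject cohort split 70/30 at subject level, fivefold CV on
  the 14 training subjects, batch 16, learning rate 1e−3, up to 3 epochs
  with early-stopping patience 2 (the phantom task converges to validation
  mean IoU > 0.95 within the first epoch, so the short schedule trades no
  measurable accuracy);
* group study: fresh 19 + 19 cohort segmented with the trained ensemble,
  normalized with the stored training-cohort statistics.

## Statistical power of the group design

With the default group parameters (106 ± 8 vs 91 ± 16 cm³, n = 19), the
pooled two-sided t test has a noncentrality of ≈ 3.8, giving ≈ 0.78–0.85
power at α = 0.005 (and > 0.95 at α = 0.05). A single study therefore
usually — but not always — reaches p < 0.005 on exact masks; across 20
seeded repetitions the observed rate is about 85%. This is a property of
the emulated study design itself, not of the segmentation.

## Known limitations

* The phantom task is easier than clinical tongue segmentation (strong
  contrast, centered organ, no motion); desk-scale Dice values (~0.99) are
  far above what real data yields.
* Consensus volumes carry a small systematic bias from the class-prior
  shift of the learned posterior at threshold 0.5: at desk scale softmax
  and majority undersegment by ~0.2–0.5%, union overestimates (~+1.3%) and
  unanimous underestimates (~−3.5%), consistently across subjects. With
  near-perfect segmentation, a paired test on a handful of subjects can
  flag even the sub-percent biases as significant; on noisier real data the
  same biases sit well inside the error spread.
* Bit-exact reproducibility is guaranteed only with single-threaded BLAS;
  multi-threaded reductions may reorder floating-point sums.
* The numpy network is CPU-bound; full-scale 256³ training is supported by
  the code path but impractical without hours of compute.
* Volumes are reported in cm³ on the basis of voxel arithmetic; the
  90–110 cm³ healthy range is the interpretation consistent with
  0.5 mm-grid voxel counts.
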