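# tongueseg

Triplanar consensus U-Net segmentation and volume quantification of the
tongue in T1-weighted head MRI.

Tongue-muscle atrophy is a clinical hallmark of bulbar involvement in motor
neuron disease; tracking it requires an operator-independent measurement of
tongue volume from routinely acquired head scans. `tongueseg` implements a
2.5-D ("triplanar") approach: a single 2-D U-Net is trained on axial,
sagittal and coronal slices pooled across subjects, a fivefold
cross-validation ensemble predicts each orientation slice-wise with fixed
validation-IoU weights

    s(v) = Σ_f w_f · p_f(v) / Σ_f w_f ,   w_f = validation mean IoU of fold f,

and the three per-voxel orientation predictions are fused into one binary
mask by one of four consensus strategies:

| strategy    | rule                                                 |
|-------------|------------------------------------------------------|
| `softmax`   | equal-weight mean of the 3 probability grids, then threshold `t` |
| `union`     | ≥ 1 orientation votes positive (after thresholding)  |
| `majority`  | ≥ 2 orientations vote positive                       |
| `unanimous` | all 3 orientations vote positive                     |

Segmentation quality is reported as precision, recall and Dice
(`2·TP/(2·TP+FP+FN)`, the harmonic mean of precision and recall), and organ
volume as positive voxels × voxel volume in cm³. Group comparisons
(e.g. atrophic patients vs controls) use Shapiro–Wilk-gated Student's t /
Mann–Whitney U tests.

Because no public tongue-MRI dataset with reference masks exists, the
package ships a synthetic phantom generator (`tongueseg.phantom`): smoothly
deformed bright ellipsoids of realistic tongue geometry (~90–110 cm³) among
near-tongue-intensity distractor blobs, with Gaussian noise and
subject-to-subject volume variation, plus exact ground-truth masks. Every
pipeline stage is testable end-to-end on phantoms; see `docs/methods.md`
for what the phantoms do and do not emulate.

## Worked example

The desk-scale study (64³ voxels at 2 mm, (8, 16, 32)-channel U-Net — the
full-scale 256³ @ 0.5 mm settings run through the same code path):

```python
from tongueseg.pipeline import run_desk_experiment, run_group_study

res = run_desk_experiment(seed=1)      # 20 phantoms, 70/30 split, fivefold CV
print(res.ensemble.weights)            # validation-IoU fold weights
print(res.summary[["strategy", "dice_mean", "precision_mean", "recall_mean"]])

grp = run_group_study(res.ensemble, seed=1)   # 19 controls vs 19 atrophic
print(grp.predicted_comparisons["softmax"])
```

On one CPU core this prints fold weights around 0.96–0.99 and, on the six
held-out test phantoms, mean Dice ≈ 0.994 for the softmax and majority
consensus (vs ≈ 0.987 for the worst single orientation, ≈ 0.992 union,
≈ 0.981 unanimous), with predicted volumes within 1% of the true phantom
volumes. The group study recovers the built-in ~14% atrophic volume
reduction: the unpaired t test on softmax-consensus volumes reports
p ≈ 4·10⁻⁴.

A command-line interface wraps the same stages (`tongueseg generate |
preprocess | train | predict | evaluate | compare | pipeline`); every run
writes its fully resolved YAML config, logs, metric CSVs, NIfTI masks and
JSON statistics into the chosen output directory, e.g.

```sh
tongueseg pipeline --seed 1 --out runs/desk
```

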