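"""End-to-end experiment drivers tying all stages together.

Two studies are provided, both fully seeded:

* :func:`run_desk_experiment` — the method-development experiment in
  miniature: a single-arm cohort of phantoms is split 70%/30% at subject
  level; the training portion is trained with fivefold cross-validation; the
  ensemble predicts the held-out test subjects with all seven variants
  (axial / sagittal / coronal, softmax / union / majority / unanimous); a
  per-subject metric table, its summary, and paired predicted-vs-truth
  volume comparisons are returned.

* :func:`run_group_study` — the application experiment: a two-arm cohort
  (healthy vs atrophic tongues) is generated, predicted with a trained
  ensemble, and the group volume difference is tested with the
  normality-gated unpaired comparison.

The desk-scale defaults below run the whole pipeline on one CPU core in
minutes: 64^3 voxels at 2 mm, a (8, 16, 32)-channel network and a short
training schedule.  The full-scale settings (256^3 @ 0.5 mm, (32, 64, 128,
256, 512) channels, 50 epochs) go through the identical code path.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .consensus import STRATEGIES, predict_subject
from .evaluation import (
    GroupComparison,
    compare_groups,
    compare_paired,
    evaluate_subject,
    summary_table,
    tongue_volume,
)
from .phantom import CohortSpec, CohortSubject, GroupSpec, PhantomSpec, generate_cohort
from .preprocess import GridSpec, preprocess_cohort
from .network import UNetConfig
from .training import ORIENTATIONS, EnsembleModel, TrainConfig, train_cv

__all__ = [
    "DESK_PHANTOM",
    "DESK_UNET",
    "DESK_TRAIN",
    "DESK_WORKING_GRID",
    "DESK_SEGMENTATION_GRID",
    "DESK_ROI",
    "DeskExperimentResult",
    "GroupStudyResult",
    "desk_cohort_spec",
    "group_cohort_spec",
    "run_desk_experiment",
    "run_group_study",
    "true_volume_group_comparison",
]

# ---------------------------------------------------------------- defaults
# Desk-scale study conditions: same physical field of view (128 mm cube) and
# tongue geometry as the full-scale setup, at 2 mm resolution.

DESK_PHANTOM = PhantomSpec(grid_shape=64, spacing_mm=2.0)
DESK_WORKING_GRID = GridSpec(64, 2.0)
DESK_SEGMENTATION_GRID = GridSpec(64, 2.0)
DESK_ROI = GridSpec(32, 2.0)
DESK_UNET = UNetConfig(encoder_channels=(8, 16, 32), dropout_rate=0.2, input_size=64)
DESK_TRAIN = TrainConfig(
    max_epochs=3, early_stop_patience=2, batch_size=16, learning_rate=1e-3, n_folds=5
)

#: healthy-tongue size distribution (volume ~106 +/- 8 cm^3, volume ~ scale^3)
CONTROL_SCALE = (1.0, 8.0 / 106.0 / 3.0)
#: atrophic arm: mean volume ~14% smaller (91 cm^3) with larger spread (sd 16)
_ATROPHIC_MEAN = (91.0 / 106.0) ** (1.0 / 3.0)
ATROPHIC_SCALE = (_ATROPHIC_MEAN, _ATROPHIC_MEAN * 16.0 / 91.0 / 3.0)


def desk_cohort_spec(n_subjects: int = 20, master_seed: int = 0,
                     template: PhantomSpec = DESK_PHANTOM) -> CohortSpec:
    """Single-arm development cohort drawn from the healthy distribution."""
    return CohortSpec(
        groups={"dev": GroupSpec(n_subjects, *CONTROL_SCALE)},
        template=template,
        master_seed=master_seed,
    )


def group_cohort_spec(n_per_group: int = 19, master_seed: int = 0,
                      template: PhantomSpec = DESK_PHANTOM) -> CohortSpec:
    """Two-arm application cohort: controls vs atrophic tongues."""
    return CohortSpec(
        groups={
            "control": GroupSpec(n_per_group, *CONTROL_SCALE),
            "atrophic": GroupSpec(n_per_group, *ATROPHIC_SCALE),
        },
        template=template,
        master_seed=master_seed + 1,  # decouple from the development cohort
    )


# ------------------------------------------------------------------ results


@dataclass
class DeskExperimentResult:
    ensemble: EnsembleModel
    manifest: pd.DataFrame
    train_subjects: list[str]
    test_subjects: list[str]
    per_subject: pd.DataFrame  # one row per (test subject, strategy)
    summary: pd.DataFrame  # summary mean +/- sd per strategy
    volume_comparisons: dict[str, GroupComparison]  # predicted vs truth, paired

    def mean_dice(self, strategy: str) -> float:
        g = self.per_subject[self.per_subject.strategy == strategy]
        return float(g.dice.mean())


@dataclass
class GroupStudyResult:
    manifest: pd.DataFrame
    predicted_volumes: dict[str, dict[str, list[float]]]  # strategy -> group -> vols
    true_comparison: GroupComparison
    predicted_comparisons: dict[str, GroupComparison]


# --------------------------------------------------------------- experiment


def _preprocess(subjects: list[CohortSubject], working, seg, roi, stats=None):
    vols = [s.volume for s in subjects]
    return preprocess_cohort(vols, working=working, seg=seg, roi=roi, stats=stats)


def run_desk_experiment(
    seed: int = 0,
    n_subjects: int = 20,
    test_fraction: float = 0.3,
    phantom: PhantomSpec = DESK_PHANTOM,
    working: GridSpec = DESK_WORKING_GRID,
    seg: GridSpec = DESK_SEGMENTATION_GRID,
    roi: GridSpec = DESK_ROI,
    unet: UNetConfig = DESK_UNET,
    train: TrainConfig = DESK_TRAIN,
    strategies: tuple[str, ...] = ORIENTATIONS + STRATEGIES,
) -> DeskExperimentResult:
    """Development experiment: 70/30 subject split, fivefold CV, all-variant
    prediction and evaluation on the untouched test subjects."""
    subjects, manifest = generate_cohort(desk_cohort_spec(n_subjects, seed, phantom))
    prepped, stats = _preprocess(subjects, working, seg, roi)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_subjects)
    n_test = max(1, int(round(test_fraction * n_subjects)))
    test_idx = sorted(int(i) for i in perm[:n_test])
    train_idx = sorted(int(i) for i in perm[n_test:])
    train_ids = [subjects[i].subject_id for i in train_idx]
    test_ids = [subjects[i].subject_id for i in test_idx]

    ensemble = train_cv(
        [prepped[i] for i in train_idx],
        unet_cfg=replace(unet, seed=seed),
        cfg=replace(train, seed=seed),
        subject_ids=train_ids,
        norm_stats=stats,
        grid=seg,
    )

    rows = []
    vol_pred: dict[str, list[float]] = {s: [] for s in strategies}
    vol_true: list[float] = []
    for i in test_idx:
        vol = prepped[i]
        masks, _ = predict_subject(ensemble, vol, batch_size=16)
        truth = vol.mask
        vol_true.append(tongue_volume(truth, vol.spacing_mm))
        for strat in strategies:
            c, m = evaluate_subject(masks[strat], truth, vol.spacing_mm)
            vol_pred[strat].append(m.volume_cm3)
            rows.append(
                {
                    "subject": subjects[i].subject_id,
                    "strategy": strat,
                    "tp": c.tp,
                    "tn": c.tn,
                    "fp": c.fp,
                    "fn": c.fn,
                    "precision": m.precision,
                    "recall": m.recall,
                    "dice": m.dice,
                    "foreground_iou": m.foreground_iou,
                    "volume_cm3": m.volume_cm3,
                    "true_volume_cm3": vol_true[-1],
                }
            )
    per_subject = pd.DataFrame(rows)
    summary = summary_table(per_subject)
    comparisons = {
        s: compare_paired(vol_pred[s], vol_true) for s in strategies
    }
    return DeskExperimentResult(
        ensemble=ensemble,
        manifest=manifest,
        train_subjects=train_ids,
        test_subjects=test_ids,
        per_subject=per_subject,
        summary=summary,
        volume_comparisons=comparisons,
    )


def run_group_study(
    ensemble: EnsembleModel,
    seed: int = 0,
    n_per_group: int = 19,
    phantom: PhantomSpec = DESK_PHANTOM,
    working: GridSpec = DESK_WORKING_GRID,
    seg: GridSpec = DESK_SEGMENTATION_GRID,
    roi: GridSpec = DESK_ROI,
    strategies: tuple[str, ...] = ("softmax", "majority"),
) -> GroupStudyResult:
    """Application experiment: segment a fresh two-arm cohort with a trained
    ensemble and test the between-group volume difference.

    New subjects are normalized with the ensemble's stored training-cohort
    statistics, mirroring how unseen clinical data would be processed.
    """
    spec = group_cohort_spec(n_per_group, seed, phantom)
    subjects, manifest = generate_cohort(spec)
    prepped, _ = _preprocess(
        subjects, working, seg, roi, stats=ensemble.norm_stats
    )
    groups = sorted(spec.groups)
    true_vols = {g: [] for g in groups}
    pred_vols: dict[str, dict[str, list[float]]] = {
        s: {g: [] for g in groups} for s in strategies
    }
    for subj, vol in zip(subjects, prepped):
        true_vols[subj.group].append(tongue_volume(vol.mask, vol.spacing_mm))
        masks, _ = predict_subject(ensemble, vol, batch_size=16)
        for s in strategies:
            pred_vols[s][subj.group].append(
                tongue_volume(masks[s], vol.spacing_mm)
            )
    g_a, g_b = groups[0], groups[-1] if len(groups) > 1 else groups[0]
    true_cmp = compare_groups(true_vols[g_a], true_vols[g_b])
    pred_cmp = {
        s: compare_groups(pred_vols[s][g_a], pred_vols[s][g_b]) for s in strategies
    }
    return GroupStudyResult(
        manifest=manifest,
        predicted_volumes=pred_vols,
        true_comparison=true_cmp,
        predicted_comparisons=pred_cmp,
    )


def true_volume_group_comparison(
    seed: int,
    n_per_group: int = 19,
    phantom: PhantomSpec = DESK_PHANTOM,
) -> GroupComparison:
    """Group comparison on exact phantom mask volumes (no segmentation);
    used to study the statistical power of the group design in isolation."""
    spec = group_cohort_spec(n_per_group, seed, phantom)
    subjects, _ = generate_cohort(spec)
    groups = sorted(spec.groups)
    vols = {g: [] for g in groups}
    for s in subjects:
        vols[s.group].append(s.true_volume_cm3)
    return compare_groups(vols[groups[0]], vols[groups[-1]])
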