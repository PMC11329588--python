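"""Triplanar slice dataset construction and fivefold cross-validated training.

A single U-Net is trained on 2-D slices pooled from all three orthogonal
orientations of every training subject, so common features are shared across
planes.  Cross-validation folds are split at the *subject* level (all slices
of a subject stay on one side), each fold trains with early stopping on the
validation loss, restores the best-epoch weights, and records its validation
mean IoU — the fixed weight later used when the fold predictions are
ensembled at inference time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .network import Adam, UNet, UNetConfig, build_unet, softmax_cross_entropy
from .preprocess import GridSpec, NormalizationStats
from .volume import CANONICAL_AXES, LabeledVolume

__all__ = [
    "ORIENTATIONS",
    "ORIENTATION_AXIS",
    "SliceBatch",
    "TrainConfig",
    "FoldResult",
    "EnsembleModel",
    "extract_slices",
    "reassemble_slices",
    "build_triplanar_dataset",
    "mean_iou",
    "train_cv",
]

#: slice orientations and the canonical (AP, LR, IS) grid axis each one is
#: perpendicular to: axial slices stack along IS, sagittal along LR, coronal
#: along AP.
ORIENTATION_AXIS: dict[str, int] = {"coronal": 0, "sagittal": 1, "axial": 2}
ORIENTATIONS: tuple[str, ...] = ("axial", "sagittal", "coronal")


@dataclass
class SliceBatch:
    """2-D slices with per-pixel integer labels and full provenance."""

    images: np.ndarray  # (N, H, W) float32
    labels: np.ndarray | None  # (N, H, W) uint8 class ids, or None
    orientation: np.ndarray  # (N,) str
    slice_index: np.ndarray  # (N,) int
    subject: np.ndarray  # (N,) str

    def __len__(self) -> int:
        return len(self.images)

    def onehot(self, idx, n_classes: int = 2) -> np.ndarray:
        lab = self.labels[idx]
        return np.eye(n_classes, dtype=np.float32)[lab]

    @classmethod
    def concatenate(cls, batches: list["SliceBatch"]) -> "SliceBatch":
        if not batches:
            raise ValueError("no slice batches to concatenate")
        return cls(
            images=np.concatenate([b.images for b in batches]),
            labels=(
                None
                if batches[0].labels is None
                else np.concatenate([b.labels for b in batches])
            ),
            orientation=np.concatenate([b.orientation for b in batches]),
            slice_index=np.concatenate([b.slice_index for b in batches]),
            subject=np.concatenate([b.subject for b in batches]),
        )


def extract_slices(vol: LabeledVolume, orientation: str, subject: str = "") -> SliceBatch:
    """All 2-D slices perpendicular to the named anatomical axis, ascending."""
    if orientation not in ORIENTATION_AXIS:
        raise ValueError(f"unknown orientation {orientation!r}")
    if tuple(vol.axis_labels) != CANONICAL_AXES:
        raise ValueError("volume must be in canonical (AP, LR, IS) orientation")
    axis = ORIENTATION_AXIS[orientation]
    images = np.ascontiguousarray(
        np.moveaxis(vol.intensity, axis, 0), dtype=np.float32
    )
    labels = None
    if vol.mask is not None:
        labels = np.ascontiguousarray(np.moveaxis(vol.mask, axis, 0)).astype(np.uint8)
    n = images.shape[0]
    return SliceBatch(
        images=images,
        labels=labels,
        orientation=np.full(n, orientation, dtype=object),
        slice_index=np.arange(n),
        subject=np.full(n, subject, dtype=object),
    )


def reassemble_slices(slices: np.ndarray, orientation: str) -> np.ndarray:
    """Inverse of :func:`extract_slices` for a full stack of slice maps."""
    if orientation not in ORIENTATION_AXIS:
        raise ValueError(f"unknown orientation {orientation!r}")
    return np.moveaxis(slices, 0, ORIENTATION_AXIS[orientation])


def build_triplanar_dataset(
    vols: list[LabeledVolume], subject_ids: list[str] | None = None
) -> SliceBatch:
    """Pool axial+sagittal+coronal slices of all subjects into one dataset.

    Requires all volumes on one cubic grid so every slice has identical
    dimensions (the reason the preprocessing resamples to a regular cube).
    """
    if not vols:
        raise ValueError("empty subject list")
    if subject_ids is None:
        subject_ids = [f"subj{i:03d}" for i in range(len(vols))]
    shapes = {v.shape for v in vols}
    if len(shapes) != 1:
        raise ValueError(f"mixed grid shapes: {shapes}")
    shape = shapes.pop()
    if len(set(shape)) != 1:
        raise ValueError("volumes must be cubic")
    batches = [
        extract_slices(v, o, subject=sid)
        for v, sid in zip(vols, subject_ids)
        for o in ORIENTATIONS
    ]
    return SliceBatch.concatenate(batches)


def mean_iou(pred_labels: np.ndarray, true_labels: np.ndarray, n_classes: int = 2) -> float:
    """Mean per-class intersection-over-union.

    A class absent from both prediction and truth is skipped (it contributes
    no information); the remaining per-class IoUs are averaged.
    """
    pred_labels = np.asarray(pred_labels)
    true_labels = np.asarray(true_labels)
    if pred_labels.shape != true_labels.shape:
        raise ValueError("shape mismatch")
    ious = []
    for c in range(n_classes):
        p = pred_labels == c
        t = true_labels == c
        union = np.logical_or(p, t).sum()
        if union == 0:
            continue
        ious.append(np.logical_and(p, t).sum() / union)
    return float(np.mean(ious)) if ious else float("nan")


# ------------------------------------------------------------------ training


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings: Adam on categorical cross-entropy, fivefold
    subject-level cross-validation, early stopping on validation loss."""

    max_epochs: int = 50
    early_stop_patience: int = 10
    batch_size: int = 16
    learning_rate: float = 1e-4
    n_folds: int = 5
    min_delta: float = 1e-5
    shared_network: bool = True  # single triplanar net; per-orientation nets not offered
    seed: int = 0

    def validate(self) -> None:
        if not self.shared_network:
            raise NotImplementedError(
                "training three orientation-specific networks is out of scope; "
                "only the shared triplanar network is implemented"
            )
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not (1 <= self.early_stop_patience < self.max_epochs):
            raise ValueError("need 1 <= patience < max_epochs")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class FoldResult:
    """One trained fold: the model, its fixed ensembling weight (validation
    mean IoU at the restored best epoch), and the training history."""

    model: UNet
    weight: float
    history: pd.DataFrame
    best_epoch: int
    train_subjects: list[str]
    val_subjects: list[str]


@dataclass
class EnsembleModel:
    """The fivefold ensemble plus everything inference needs to reproduce
    the training-time preprocessing."""

    folds: list[FoldResult]
    unet_config: UNetConfig
    train_config: TrainConfig
    norm_stats: NormalizationStats | None = None
    grid: GridSpec | None = None

    @property
    def weights(self) -> np.ndarray:
        return np.array([f.weight for f in self.folds], dtype=np.float64)

    def manifest(self) -> dict:
        return {
            "n_folds": len(self.folds),
            "fold_weights": [float(f.weight) for f in self.folds],
            "best_epochs": [int(f.best_epoch) for f in self.folds],
            "val_subjects": [list(f.val_subjects) for f in self.folds],
            "seed": self.train_config.seed,
        }


def _evaluate(model: UNet, batch: SliceBatch, batch_size: int):
    """Validation loss and pooled 2-class mean IoU, dropout inactive."""
    n_classes = model.cfg.n_classes
    total_loss = 0.0
    inter = np.zeros(n_classes)
    union = np.zeros(n_classes)
    n = len(batch)
    for start in range(0, n, batch_size):
        idx = slice(start, min(start + batch_size, n))
        logits, _ = model.forward(batch.images[idx], train=False)
        onehot = batch.onehot(idx, n_classes)
        loss, probs, _ = softmax_cross_entropy(logits, onehot)
        total_loss += loss * (idx.stop - idx.start)
        pred = probs.argmax(axis=-1)
        true = batch.labels[idx]
        for c in range(n_classes):
            p = pred == c
            t = true == c
            inter[c] += np.logical_and(p, t).sum()
            union[c] += np.logical_or(p, t).sum()
    present = union > 0
    miou = float(np.mean(inter[present] / union[present]))
    return total_loss / n, miou


def _train_fold(
    unet_cfg: UNetConfig,
    train_batch: SliceBatch,
    val_batch: SliceBatch,
    cfg: TrainConfig,
    fold_seed: int,
):
    model = build_unet(replace(unet_cfg, seed=fold_seed))
    opt = Adam(model.params, lr=cfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([fold_seed, 7]))
    best_loss = np.inf
    best_state = model.state_dict()
    best_epoch = -1
    best_miou = 0.0
    since_improve = 0
    rows = []
    n = len(train_batch)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            x = train_batch.images[idx]
            y = train_batch.onehot(idx, unet_cfg.n_classes)
            loss, grads = model.loss_and_grads(x, y, rng=rng)
            opt.step(grads)
            epoch_loss += loss * len(idx)
        val_loss, val_miou = _evaluate(model, val_batch, cfg.batch_size)
        rows.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / n,
                "val_loss": val_loss,
                "val_mean_iou": val_miou,
            }
        )
        if val_loss < best_loss - cfg.min_delta:
            best_loss = val_loss
            best_state = model.state_dict()
            best_epoch = epoch
            best_miou = val_miou
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= cfg.early_stop_patience:
                break
    model.load_state_dict(best_state)
    return model, best_miou, pd.DataFrame(rows), best_epoch


def train_cv(
    vols: list[LabeledVolume],
    unet_cfg: UNetConfig,
    cfg: TrainConfig = TrainConfig(),
    subject_ids: list[str] | None = None,
    norm_stats: NormalizationStats | None = None,
    grid: GridSpec | None = None,
) -> EnsembleModel:
    """K-fold cross-validated training of the shared triplanar network.

    Subjects are permuted with the seeded generator and split into
    ``n_folds`` groups; fold *f* validates on group *f* and trains on the
    rest, so each subject is held out exactly once and no subject's slices
    leak across the split.
    """
    cfg.validate()
    unet_cfg.validate()
    if subject_ids is None:
        subject_ids = [f"subj{i:03d}" for i in range(len(vols))]
    if len(vols) < cfg.n_folds:
        raise ValueError("fewer subjects than folds")
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(len(vols))
    fold_assign = np.array_split(perm, cfg.n_folds)
    folds: list[FoldResult] = []
    for f, val_idx in enumerate(fold_assign):
        val_set = set(int(i) for i in val_idx)
        train_ids = [subject_ids[i] for i in range(len(vols)) if i not in val_set]
        val_ids = [subject_ids[i] for i in sorted(val_set)]
        train_batch = build_triplanar_dataset(
            [vols[i] for i in range(len(vols)) if i not in val_set], train_ids
        )
        val_batch = build_triplanar_dataset(
            [vols[i] for i in sorted(val_set)], val_ids
        )
        fold_seed = int(np.random.SeedSequence([cfg.seed, f]).generate_state(1)[0] % (2**31))
        model, w_f, history, best_epoch = _train_fold(
            unet_cfg, train_batch, val_batch, cfg, fold_seed
        )
        folds.append(
            FoldResult(
                model=model,
                weight=w_f,
                history=history,
                best_epoch=best_epoch,
                train_subjects=train_ids,
                val_subjects=val_ids,
            )
        )
    return EnsembleModel(
        folds=folds,
        unet_config=unet_cfg,
        train_config=cfg,
        norm_stats=norm_stats,
        grid=grid,
    )
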