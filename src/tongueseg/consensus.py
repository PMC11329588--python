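"""Inference: slice-wise triplanar prediction, IoU-weighted fold ensembling,
and orientation fusion.

For each orientation the volume is cut into 2-D slices, every fold model
predicts per-pixel foreground probabilities, and the fold outputs are
combined as a weighted average with the fixed validation-IoU weights.  The
three per-orientation probability grids are then merged into one binary
segmentation by one of four strategies:

* ``softmax`` — equal-weight average of the three probability grids, then
  thresholded;
* ``union`` / ``majority`` / ``unanimous`` — each orientation thresholded to
  a hard mask first, then a voxel is kept if at least one / at least two /
  all three orientations voted for it.

With hard (0/1) inputs and equal weights, softmax averaging and majority
voting coincide; with soft probabilities they can differ (a single confident
orientation can push the average over the threshold while being outvoted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .training import ORIENTATIONS, EnsembleModel, extract_slices, reassemble_slices
from .volume import LabeledVolume

__all__ = [
    "STRATEGIES",
    "OrientationPrediction",
    "ConsensusConfig",
    "ensemble_softmax",
    "predict_orientation",
    "harden",
    "merge_consensus",
    "predict_subject",
]

STRATEGIES: tuple[str, ...] = ("softmax", "union", "majority", "unanimous")


@dataclass
class OrientationPrediction:
    """Per-voxel foreground probability grid reassembled from one plane."""

    orientation: str
    softmax_score: np.ndarray  # 3-D float array in [0, 1]


@dataclass(frozen=True)
class ConsensusConfig:
    """Fusion strategy plus the hard-prediction threshold ``t``."""

    strategy: str = "softmax"
    threshold: float = 0.5

    def validate(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie strictly between 0 and 1")


def ensemble_softmax(fold_probs: list[np.ndarray], weights: list[float]) -> np.ndarray:
    """Weighted average of fold probability grids, s = sum(w*p) / sum(w)."""
    if len(fold_probs) != len(weights):
        raise ValueError("one weight per fold required")
    if not fold_probs:
        raise ValueError("no fold predictions")
    w = np.asarray(weights, dtype=np.float64)
    if np.any(w <= 0):
        raise ValueError("fold weights must be strictly positive")
    shapes = {p.shape for p in fold_probs}
    if len(shapes) != 1:
        raise ValueError("fold predictions must share one shape")
    acc = np.zeros(fold_probs[0].shape, dtype=np.float64)
    for wf, p in zip(w, fold_probs):
        acc += wf * p
    return (acc / w.sum()).astype(np.float32)


def predict_orientation(
    ens: EnsembleModel,
    vol: LabeledVolume,
    orientation: str,
    batch_size: int = 32,
) -> OrientationPrediction:
    """Fold-ensembled foreground probabilities for one slice orientation.

    The volume must already be preprocessed onto the ensemble's segmentation
    grid (with the stored cohort normalization statistics).
    """
    if ens.grid is not None and vol.shape != (ens.grid.matrix,) * 3:
        raise ValueError(
            f"volume shape {vol.shape} does not match ensemble grid "
            f"{(ens.grid.matrix,) * 3}"
        )
    batch = extract_slices(vol, orientation)
    fold_probs = [
        f.model.predict(batch.images, batch_size=batch_size)[..., 1]
        for f in ens.folds
    ]
    fused = ensemble_softmax(fold_probs, [f.weight for f in ens.folds])
    return OrientationPrediction(
        orientation=orientation,
        softmax_score=reassemble_slices(fused, orientation),
    )


def harden(p: np.ndarray, t: float = 0.5) -> np.ndarray:
    """Threshold a probability grid; a voxel exactly at ``t`` is positive."""
    if not (0.0 < t < 1.0):
        raise ValueError("threshold must lie strictly between 0 and 1")
    return (np.asarray(p) >= t).astype(np.uint8)


def merge_consensus(
    preds: list[OrientationPrediction] | list[np.ndarray],
    cfg: ConsensusConfig = ConsensusConfig(),
) -> np.ndarray:
    """Fuse the three orientation predictions into one binary mask."""
    cfg.validate()
    if len(preds) != 3:
        raise ValueError("exactly three orientation predictions required")
    grids = [
        p.softmax_score if isinstance(p, OrientationPrediction) else np.asarray(p)
        for p in preds
    ]
    shapes = {g.shape for g in grids}
    if len(shapes) != 1:
        raise ValueError("orientation predictions must share one shape")
    if cfg.strategy == "softmax":
        mean = (
            grids[0].astype(np.float64)
            + grids[1].astype(np.float64)
            + grids[2].astype(np.float64)
        ) / 3.0
        return harden(mean, cfg.threshold)
    votes = sum(harden(g, cfg.threshold).astype(np.int8) for g in grids)
    needed = {"union": 1, "majority": 2, "unanimous": 3}[cfg.strategy]
    return (votes >= needed).astype(np.uint8)


def predict_subject(
    ens: EnsembleModel,
    vol: LabeledVolume,
    threshold: float = 0.5,
    batch_size: int = 32,
) -> tuple[dict[str, np.ndarray], dict[str, OrientationPrediction]]:
    """All seven prediction variants for one subject.

    Returns ``(masks, orientation_preds)`` where ``masks`` has one binary
    mask per single orientation (axial, sagittal, coronal — each hardened on
    its own) and per consensus strategy (softmax, union, majority,
    unanimous).
    """
    preds = {
        o: predict_orientation(ens, vol, o, batch_size=batch_size)
        for o in ORIENTATIONS
    }
    masks: dict[str, np.ndarray] = {
        o: harden(preds[o].softmax_score, threshold) for o in ORIENTATIONS
    }
    triple = [preds[o] for o in ORIENTATIONS]
    for strat in STRATEGIES:
        masks[strat] = merge_consensus(
            triple, ConsensusConfig(strategy=strat, threshold=threshold)
        )
    return masks, preds
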