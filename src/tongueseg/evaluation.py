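"""Voxel-level evaluation, volume quantification, reporting and statistics.

Segmentation quality is summarized by the confusion counts (TP/TN/FP/FN) over
the whole evaluation grid and the derived precision, recall, Dice (= F1) and
foreground IoU.  Organ volume is the positive-voxel count times the voxel
volume, reported in cm^3.  Group statistics follow the conventional
normality-gated scheme: Shapiro-Wilk at 0.05 decides between the parametric
(paired/unpaired Student's t) and the rank-based (Wilcoxon signed-rank /
Mann-Whitney U) test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "GroupComparison",
    "confusion",
    "metrics",
    "tongue_volume",
    "overlay_slice",
    "compare_paired",
    "compare_groups",
    "summary_table",
    "evaluate_subject",
]

NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxel counts; TP+TN+FP+FN equals the size of the evaluation grid."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Derived metrics; a ``None`` entry means the denominator was empty."""

    precision: float | None
    recall: float | None
    dice: float | None
    foreground_iou: float | None
    volume_cm3: float | None = None


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of a normality-gated two-sample (or paired) comparison."""

    test_name: str
    statistic: float | None
    p_value: float | None
    normality_p: tuple[float, ...]
    group_means: tuple[float, ...]
    group_sds: tuple[float, ...]
    degenerate: bool = False
    note: str = ""


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.all(np.isin(arr, (0, 1))):
        raise ValueError(f"{name} must be binary")
    return arr.astype(bool)


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Voxel-wise confusion counts between two binary masks."""
    p = _check_binary(pred, "pred")
    t = _check_binary(truth, "truth")
    if p.shape != t.shape:
        raise ValueError("shape mismatch between prediction and truth")
    tp = int(np.logical_and(p, t).sum())
    fp = int(np.logical_and(p, ~t).sum())
    fn = int(np.logical_and(~p, t).sum())
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Precision, recall, Dice and foreground IoU from confusion counts.

    Undefined ratios (zero denominator) are reported as ``None`` rather than
    0 so cohort averages stay honest.
    """
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    denom = 2 * c.tp + c.fp + c.fn
    dice = 2 * c.tp / denom if denom > 0 else None
    iou_denom = c.tp + c.fp + c.fn
    fg_iou = c.tp / iou_denom if iou_denom > 0 else None
    return MetricsReport(precision=precision, recall=recall, dice=dice, foreground_iou=fg_iou)


def tongue_volume(mask: np.ndarray, spacing_mm: tuple[float, float, float] | float) -> float:
    """Segmented volume in cm^3: positive voxels times voxel volume."""
    m = _check_binary(mask, "mask")
    if np.isscalar(spacing_mm):
        spacing_mm = (float(spacing_mm),) * 3
    if any(s <= 0 for s in spacing_mm):
        raise ValueError("spacing must be positive")
    voxel_mm3 = float(np.prod(spacing_mm))
    return float(m.sum()) * voxel_mm3 / 1000.0


def evaluate_subject(
    pred: np.ndarray,
    truth: np.ndarray,
    spacing_mm: tuple[float, float, float] | float,
) -> tuple[ConfusionCounts, MetricsReport]:
    """Confusion counts plus full metrics report (with predicted volume)."""
    c = confusion(pred, truth)
    m = metrics(c)
    return c, MetricsReport(
        precision=m.precision,
        recall=m.recall,
        dice=m.dice,
        foreground_iou=m.foreground_iou,
        volume_cm3=tongue_volume(pred, spacing_mm),
    )


# ------------------------------------------------------------------ overlay

_TP_COLOR = np.array([1.0, 0.0, 1.0])  # magenta
_FP_COLOR = np.array([0.0, 0.0, 1.0])  # blue
_FN_COLOR = np.array([1.0, 1.0, 0.0])  # yellow


def overlay_slice(
    pred: np.ndarray, truth: np.ndarray, intensity: np.ndarray, alpha: float = 0.6
) -> np.ndarray:
    """Color-coded agreement overlay on a grayscale slice.

    Matching foreground pixels are magenta, false positives blue, false
    negatives yellow; returns an (H, W, 3) float RGB image in [0, 1].
    """
    p = _check_binary(pred, "pred")
    t = _check_binary(truth, "truth")
    if p.shape != t.shape or p.shape != intensity.shape:
        raise ValueError("shape mismatch")
    lo, hi = float(intensity.min()), float(intensity.max())
    gray = (intensity - lo) / (hi - lo) if hi > lo else np.zeros_like(intensity, dtype=float)
    img = np.repeat(gray[..., None], 3, axis=-1)
    for sel, color in (
        (p & t, _TP_COLOR),
        (p & ~t, _FP_COLOR),
        (~p & t, _FN_COLOR),
    ):
        img[sel] = (1 - alpha) * img[sel] + alpha * color
    return img


# --------------------------------------------------------------- statistics


def _summary(x: np.ndarray) -> tuple[float, float]:
    return float(np.mean(x)), float(np.std(x, ddof=1)) if len(x) > 1 else 0.0


def compare_paired(values_a: list[float], values_b: list[float]) -> GroupComparison:
    """Paired comparison (e.g. predicted vs ground-truth volumes).

    Shapiro-Wilk on the paired differences gates the choice: paired
    Student's t when normality is not rejected at 0.05, Wilcoxon signed-rank
    otherwise.  Zero-variance differences are reported as degenerate (no
    difference when all differences are zero).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    diff = a - b
    means = (float(a.mean()), float(b.mean()))
    sds = (_summary(a)[1], _summary(b)[1])
    if np.allclose(diff.std(ddof=1), 0.0):
        no_diff = bool(np.allclose(diff, 0.0))
        return GroupComparison(
            test_name="paired t",
            statistic=None,
            p_value=1.0 if no_diff else None,
            normality_p=(float("nan"),),
            group_means=means,
            group_sds=sds,
            degenerate=True,
            note="zero-variance differences" + (" (identical samples)" if no_diff else ""),
        )
    sw = sps.shapiro(diff)
    if sw.pvalue >= NORMALITY_ALPHA:
        res = sps.ttest_rel(a, b)
        name = "paired t"
    else:
        res = sps.wilcoxon(a, b)
        name = "Wilcoxon signed-rank"
    return GroupComparison(
        test_name=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        normality_p=(float(sw.pvalue),),
        group_means=means,
        group_sds=sds,
    )


def compare_groups(values_a: list[float], values_b: list[float]) -> GroupComparison:
    """Two independent groups: Shapiro-Wilk per group at 0.05, then unpaired
    Student's t (pooled variance) if both pass, Mann-Whitney U otherwise."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 values")
    sw_a = sps.shapiro(a)
    sw_b = sps.shapiro(b)
    means = (float(a.mean()), float(b.mean()))
    sds = (_summary(a)[1], _summary(b)[1])
    if sw_a.pvalue >= NORMALITY_ALPHA and sw_b.pvalue >= NORMALITY_ALPHA:
        res = sps.ttest_ind(a, b, equal_var=True)
        name = "unpaired t"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "Mann-Whitney U"
    return GroupComparison(
        test_name=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        normality_p=(float(sw_a.pvalue), float(sw_b.pvalue)),
        group_means=means,
        group_sds=sds,
    )


# ---------------------------------------------------------------- reporting


def summary_table(per_subject: pd.DataFrame) -> pd.DataFrame:
    """Strategy-by-metric summary table (mean +/- sd over subjects).

    ``per_subject`` must carry one row per (subject, strategy) with columns
    ``subject, strategy, tp, tn, fp, fn, precision, recall, dice``.  The
    summary averages *per-subject* metrics (not metrics of pooled counts),
    the convention used for small-cohort segmentation tables.
    """
    required = {"subject", "strategy", "tp", "tn", "fp", "fn", "precision", "recall", "dice"}
    missing = required - set(per_subject.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    subject_sets = {
        s: frozenset(g["subject"]) for s, g in per_subject.groupby("strategy")
    }
    if len(set(subject_sets.values())) != 1:
        raise ValueError("inconsistent subject sets across strategies")
    rows = []
    for strategy, g in per_subject.groupby("strategy", sort=False):
        row: dict = {"strategy": strategy, "n_subjects": len(g)}
        for col in ("tp", "tn", "fp", "fn", "precision", "recall", "dice"):
            vals = g[col].astype(float).dropna()
            row[f"{col}_mean"] = float(vals.mean()) if len(vals) else float("nan")
            row[f"{col}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
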