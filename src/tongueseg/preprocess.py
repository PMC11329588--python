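"""Preprocessing chain: isotropic resampling, landmark-centered reorientation,
cohort z-score intensity normalization, and crop/upsample to the segmentation
grid.

The canonical pipeline mirrors routine head-MRI preparation for slice-wise
segmentation:

1. resample to a *working grid* of 256^3 voxels at 1.0 mm isotropic;
2. translate the volume so an anatomical landmark (palatal tip; for phantoms,
   the tongue centroid) sits at the matrix center, with axes permuted/flipped
   into the canonical (AP, LR, IS) order;
3. z-score normalize intensities with cohort statistics: the mean M and the
   sample standard deviation S of the *per-subject mean intensities* over a
   tongue-centered 128^3 (1 mm) ROI, applied identically to every subject as
   (x - M) / S;
4. crop the central 128 mm cube and resample it to the *segmentation grid* of
   256^3 voxels at 0.5 mm, on which slices are fed to the network.

All grids are cubic so slices from the three orientations share dimensions —
the prerequisite for training a single network on all three planes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .volume import CANONICAL_AXES, LabeledVolume

__all__ = [
    "GridSpec",
    "NormalizationStats",
    "WORKING_GRID",
    "SEGMENTATION_GRID",
    "NORMALIZATION_ROI",
    "resample_isotropic",
    "reorient_center",
    "compute_cohort_stats",
    "znormalize",
    "znormalize_per_subject",
    "to_segmentation_grid",
    "from_segmentation_grid",
    "preprocess_cohort",
]


@dataclass(frozen=True)
class GridSpec:
    """Cubic grid: ``matrix`` voxels per axis at isotropic ``spacing_mm``."""

    matrix: int
    spacing_mm: float

    def validate(self) -> None:
        if self.matrix < 2:
            raise ValueError("matrix must be >= 2")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")

    @property
    def extent_mm(self) -> float:
        return self.matrix * self.spacing_mm


WORKING_GRID = GridSpec(256, 1.0)
SEGMENTATION_GRID = GridSpec(256, 0.5)
#: tongue-centered ROI over which per-subject mean intensities are taken
NORMALIZATION_ROI = GridSpec(128, 1.0)


@dataclass
class NormalizationStats:
    """Cohort intensity statistics: mean/SD of per-subject ROI means."""

    per_subject_roi_means: list[float]
    cohort_mean: float
    cohort_std: float
    roi_shape: tuple[int, int, int]

    def validate(self) -> None:
        if self.cohort_std <= 0:
            raise ValueError("cohort_std must be > 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "per_subject_roi_means": list(map(float, self.per_subject_roi_means)),
                    "cohort_mean": float(self.cohort_mean),
                    "cohort_std": float(self.cohort_std),
                    "roi_shape": list(self.roi_shape),
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationStats":
        d = json.loads(Path(path).read_text())
        return cls(
            per_subject_roi_means=d["per_subject_roi_means"],
            cohort_mean=d["cohort_mean"],
            cohort_std=d["cohort_std"],
            roi_shape=tuple(d["roi_shape"]),
        )


# ----------------------------------------------------------------- resampling


def resample_isotropic(
    vol: LabeledVolume, target: GridSpec, fill: float = 0.0
) -> LabeledVolume:
    """Resample onto a cubic isotropic grid, preserving the physical center.

    Intensity is tri-linearly interpolated; the mask is interpolated as a
    float field and re-binarized at 0.5 (ties count as foreground).  The
    physical field of view stays centered: voxel ``j`` of the target maps to
    physical coordinate ``(j - (N_t-1)/2) * s_t`` relative to the volume
    center, and regions outside the input are padded with ``fill``.
    """
    target.validate()
    shape = vol.shape
    if (
        shape == (target.matrix,) * 3
        and all(abs(s - target.spacing_mm) < 1e-12 for s in vol.spacing_mm)
    ):
        return vol.copy()

    scale = np.array([target.spacing_mm / s for s in vol.spacing_mm])
    offset = np.array(
        [
            (n_in - 1) / 2.0 - sc * (target.matrix - 1) / 2.0
            for n_in, sc in zip(shape, scale)
        ]
    )
    out_shape = (target.matrix,) * 3
    src = vol.intensity
    if not np.issubdtype(src.dtype, np.floating):
        src = src.astype(np.float32)
    intensity = ndi.affine_transform(
        src,
        np.diag(scale),
        offset=offset,
        output_shape=out_shape,
        order=1,
        mode="constant",
        cval=fill,
    )
    mask = None
    if vol.mask is not None:
        maskf = ndi.affine_transform(
            vol.mask.astype(np.float32),
            np.diag(scale),
            offset=offset,
            output_shape=out_shape,
            order=1,
            mode="constant",
            cval=0.0,
        )
        mask = (maskf >= 0.5).astype(np.uint8)
    return LabeledVolume(
        intensity=intensity,
        mask=mask,
        spacing_mm=(target.spacing_mm,) * 3,
        axis_labels=vol.axis_labels,
    )


# --------------------------------------------------------------- reorientation


def _canonicalize_axes(vol: LabeledVolume, landmark: np.ndarray):
    """Permute/flip grid axes so axis_labels match (AP, LR, IS)."""
    labels = list(vol.axis_labels)
    perm = []
    flips = []
    for want in CANONICAL_AXES:
        if want in labels:
            ax = labels.index(want)
            perm.append(ax)
            flips.append(False)
        elif want[::-1] in labels:
            ax = labels.index(want[::-1])
            perm.append(ax)
            flips.append(True)
        else:
            raise ValueError(f"axis label {want!r} not found in {vol.axis_labels}")

    intensity = np.transpose(vol.intensity, perm)
    mask = None if vol.mask is None else np.transpose(vol.mask, perm)
    spacing = tuple(vol.spacing_mm[p] for p in perm)
    lm = np.asarray(landmark, dtype=float)[list(perm)]
    for ax, flip in enumerate(flips):
        if flip:
            intensity = np.flip(intensity, axis=ax)
            if mask is not None:
                mask = np.flip(mask, axis=ax)
            lm[ax] = intensity.shape[ax] - 1 - lm[ax]
    return intensity.copy(), (None if mask is None else mask.copy()), spacing, lm


def _integer_shift(arr: np.ndarray, shift: np.ndarray, fill) -> np.ndarray:
    out = np.full_like(arr, fill)
    src = []
    dst = []
    for ax, sh in enumerate(shift):
        n = arr.shape[ax]
        sh = int(sh)
        if abs(sh) >= n:
            return out
        if sh >= 0:
            src.append(slice(0, n - sh))
            dst.append(slice(sh, n))
        else:
            src.append(slice(-sh, n))
            dst.append(slice(0, n + sh))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def reorient_center(
    vol: LabeledVolume,
    landmark: tuple[int, int, int] | tuple[float, float, float],
    fill: float = 0.0,
) -> LabeledVolume:
    """Put ``landmark`` (voxel coordinate in ``vol``'s own axes) at the matrix
    center and canonicalize the axis order/direction.

    The translation is an integer-voxel shift (no interpolation); vacated
    voxels are filled with ``fill`` (intensity) / background (mask).
    """
    lm = np.asarray(landmark, dtype=float)
    if np.any(lm < 0) or np.any(lm > np.asarray(vol.shape) - 1):
        raise ValueError("landmark outside the grid")
    intensity, mask, spacing, lm = _canonicalize_axes(vol, lm)
    center = np.array([n // 2 for n in intensity.shape])
    shift = np.rint(center - lm).astype(int)
    intensity = _integer_shift(intensity, shift, fill)
    if mask is not None:
        mask = _integer_shift(mask, shift, 0)
    return LabeledVolume(
        intensity=intensity, mask=mask, spacing_mm=spacing, axis_labels=CANONICAL_AXES
    )


# ---------------------------------------------------------------- z-scoring


def _central_roi_mean(vol: LabeledVolume, roi: GridSpec) -> float:
    slices = []
    for ax in range(3):
        width = int(round(roi.extent_mm / vol.spacing_mm[ax]))
        n = vol.shape[ax]
        width = min(width, n)
        start = (n - width) // 2
        slices.append(slice(start, start + width))
    return float(vol.intensity[tuple(slices)].mean(dtype=np.float64))


def compute_cohort_stats(
    vols: list[LabeledVolume], roi: GridSpec = NORMALIZATION_ROI
) -> NormalizationStats:
    """Cohort normalization statistics from tongue-centered ROI means.

    Each subject contributes the mean intensity over the central ROI (the
    same physical region for all subjects, assuming centered volumes); M and
    S are the mean and the sample (n-1) standard deviation of those means.
    """
    if len(vols) < 2:
        raise ValueError("cohort statistics need >= 2 subjects")
    shapes = {v.shape for v in vols}
    if len(shapes) != 1:
        raise ValueError("all volumes must share one grid")
    means = [_central_roi_mean(v, roi) for v in vols]
    m = float(np.mean(means))
    s = float(np.std(means, ddof=1))
    if s <= 0:
        raise ValueError("cohort std of ROI means is zero; z-scoring undefined")
    width = int(round(roi.extent_mm / vols[0].spacing_mm[0]))
    return NormalizationStats(
        per_subject_roi_means=means, cohort_mean=m, cohort_std=s, roi_shape=(width,) * 3
    )


def znormalize(vol: LabeledVolume, stats: NormalizationStats) -> LabeledVolume:
    """Apply cohort z-scoring ``x -> (x - M) / S``; the mask is untouched."""
    stats.validate()
    out = vol.copy()
    # float64 so the normalization identities (cohort mean/sd of ROI means
    # exactly 0/1) survive the round trip; slice extraction narrows to
    # float32 at the network boundary
    out.intensity = (
        (vol.intensity.astype(np.float64) - stats.cohort_mean) / stats.cohort_std
    )
    return out


def znormalize_per_subject(vol: LabeledVolume, roi: GridSpec = NORMALIZATION_ROI) -> LabeledVolume:
    """Alternative reading of cohort normalization: each subject scaled by its
    own ROI mean and ROI standard deviation.  Off the default path; provided
    as a config switch."""
    sub = []
    for ax in range(3):
        width = min(int(round(roi.extent_mm / vol.spacing_mm[ax])), vol.shape[ax])
        start = (vol.shape[ax] - width) // 2
        sub.append(slice(start, start + width))
    region = vol.intensity[tuple(sub)]
    m = float(region.mean())
    s = float(region.std(ddof=1))
    if s <= 0:
        raise ValueError("ROI standard deviation is zero")
    out = vol.copy()
    out.intensity = (vol.intensity.astype(np.float32) - m) / s
    return out


# ------------------------------------------------------- segmentation grid


def _central_crop(vol: LabeledVolume, extent_mm: float) -> LabeledVolume:
    slices = []
    for ax in range(3):
        width = int(round(extent_mm / vol.spacing_mm[ax]))
        n = vol.shape[ax]
        if width > n:
            raise ValueError("segmentation extent exceeds working extent")
        start = (n - width) // 2
        slices.append(slice(start, start + width))
    sl = tuple(slices)
    return LabeledVolume(
        intensity=vol.intensity[sl].copy(),
        mask=None if vol.mask is None else vol.mask[sl].copy(),
        spacing_mm=vol.spacing_mm,
        axis_labels=vol.axis_labels,
    )


def to_segmentation_grid(
    vol: LabeledVolume, seg: GridSpec = SEGMENTATION_GRID, fill: float = 0.0
) -> LabeledVolume:
    """Crop the central region of physical extent ``seg.matrix * seg.spacing``
    and resample it onto the segmentation grid (canonically: the central
    128 mm cube of the working grid, upsampled to 256^3 @ 0.5 mm)."""
    seg.validate()
    cropped = _central_crop(vol, seg.extent_mm)
    return resample_isotropic(cropped, seg, fill=fill)


def from_segmentation_grid(
    vol: LabeledVolume, working: GridSpec = WORKING_GRID, fill: float = 0.0
) -> LabeledVolume:
    """Inverse mapping: place a segmentation-grid volume back into the center
    of the working grid (downsampling to the working spacing first)."""
    working.validate()
    width = int(round(vol.shape[0] * vol.spacing_mm[0] / working.spacing_mm))
    intermediate = resample_isotropic(vol, GridSpec(width, working.spacing_mm), fill=fill)
    out_int = np.full((working.matrix,) * 3, fill, dtype=np.float32)
    out_mask = None if vol.mask is None else np.zeros((working.matrix,) * 3, dtype=np.uint8)
    start = (working.matrix - width) // 2
    sl = tuple(slice(start, start + width) for _ in range(3))
    out_int[sl] = intermediate.intensity
    if out_mask is not None:
        out_mask[sl] = intermediate.mask
    return LabeledVolume(
        intensity=out_int,
        mask=out_mask,
        spacing_mm=(working.spacing_mm,) * 3,
        axis_labels=vol.axis_labels,
    )


# ----------------------------------------------------------------- pipeline


def preprocess_cohort(
    vols: list[LabeledVolume],
    landmarks: list[tuple[float, float, float]] | None = None,
    working: GridSpec = WORKING_GRID,
    seg: GridSpec = SEGMENTATION_GRID,
    roi: GridSpec = NORMALIZATION_ROI,
    stats: NormalizationStats | None = None,
) -> tuple[list[LabeledVolume], NormalizationStats]:
    """Full chain for a cohort: resample -> recenter -> z-score -> seg grid.

    When ``landmarks`` is ``None`` the mask centroid is used (the phantom path);
    pass stored landmark coordinates for real data.  Pass pre-computed
    ``stats`` (e.g. the training cohort's) to normalize new data consistently.
    """
    resampled = [resample_isotropic(v, working) for v in vols]
    centered = []
    for i, v in enumerate(resampled):
        if landmarks is not None:
            lm = landmarks[i]
        else:
            if v.mask is None:
                raise ValueError("no landmark given and volume has no mask")
            lm = tuple(np.mean(np.nonzero(v.mask), axis=1))
        centered.append(reorient_center(v, lm))
    if stats is None:
        stats = compute_cohort_stats(centered, roi)
    normalized = [znormalize(v, stats) for v in centered]
    return [to_segmentation_grid(v, seg) for v in normalized], stats
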