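"""Core volumetric container used throughout the pipeline.

A :class:`LabeledVolume` is a 3-D scalar intensity grid with isotropic or
anisotropic voxel spacing, anatomical axis labels, and (optionally) a binary
ground-truth mask on the same grid.  Axis labels follow the radiological
shorthand used in the rest of the package: ``AP`` (anterior->posterior),
``LR`` (left->right), ``IS`` (inferior->superior).  The canonical in-memory
axis order is ``(AP, LR, IS)``: axial slices are taken perpendicular to the
``IS`` axis, sagittal perpendicular to ``LR`` and coronal perpendicular to
``AP``.

Volumes are exchanged on disk as NIfTI-1 files with the voxel spacing on the
diagonal of the affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

#: canonical anatomical axis order for in-memory grids
CANONICAL_AXES: tuple[str, str, str] = ("AP", "LR", "IS")


@dataclass
class LabeledVolume:
    """3-D intensity grid plus optional binary truth mask.

    Parameters
    ----------
    intensity:
        3-D float array of MR-like intensities (arbitrary units).
    mask:
        Binary 3-D array of the same shape (1 = tongue), or ``None`` when no
        ground truth is available.
    spacing_mm:
        Per-axis voxel edge length in millimetres.
    axis_labels:
        Anatomical direction of each grid axis, e.g. ``("AP", "LR", "IS")``.
        A reversed direction is written with the letters swapped (``"PA"``).
    """

    intensity: np.ndarray
    mask: np.ndarray | None
    spacing_mm: tuple[float, float, float]
    axis_labels: tuple[str, str, str] = field(default=CANONICAL_AXES)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be a 3-D array")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be three strictly positive values")
        self.axis_labels = tuple(self.axis_labels)
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.intensity.shape:
                raise ValueError("mask and intensity shapes differ")
            vals = np.unique(self.mask)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("mask must be binary (values in {0, 1})")
            self.mask = self.mask.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def copy(self) -> "LabeledVolume":
        return replace(
            self,
            intensity=self.intensity.copy(),
            mask=None if self.mask is None else self.mask.copy(),
        )

    # ------------------------------------------------------------------ I/O

    def _affine(self) -> np.ndarray:
        return np.diag([*self.spacing_mm, 1.0])

    def save(self, intensity_path: str | Path, mask_path: str | Path | None = None) -> None:
        """Write intensity (and mask, if present) as NIfTI-1 files."""
        aff = self._affine()
        nib.save(nib.Nifti1Image(self.intensity.astype(np.float32), aff), str(intensity_path))
        if mask_path is not None:
            if self.mask is None:
                raise ValueError("volume carries no mask to save")
            nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), aff), str(mask_path))

    @classmethod
    def load(
        cls,
        intensity_path: str | Path,
        mask_path: str | Path | None = None,
        axis_labels: tuple[str, str, str] = CANONICAL_AXES,
    ) -> "LabeledVolume":
        img = nib.load(str(intensity_path))
        intensity = np.asanyarray(img.dataobj).astype(np.float32)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        mask = None
        if mask_path is not None:
            mimg = nib.load(str(mask_path))
            mask = (np.asanyarray(mimg.dataobj) >= 0.5).astype(np.uint8)
        return cls(intensity=intensity, mask=mask, spacing_mm=spacing, axis_labels=axis_labels)
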