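"""Synthetic head/tongue phantom generator.

Clinical T1-weighted head MRI with manual tongue labels cannot be shipped, so
this module generates volumes whose statistical structure mirrors the data the
pipeline is designed for: a bright, smoothly deformed ellipsoidal "tongue"
centered in the matrix, a handful of adjacent soft-tissue distractor blobs of
near-tongue intensity (emulating the hard-to-separate lip/soft-palate pixels),
additive Gaussian noise, and subject-to-subject variation of tongue volume.

The exact voxelized mask of the deformed ellipsoid is returned alongside the
intensity, so every downstream stage (preprocessing, training, consensus
fusion, evaluation) can be tested against a known truth.

The default tongue semi-axes (35.75, 23.75, 30.0) mm along (AP, LR, IS)
reproduce the typical in-vivo extent of the organ: about 143 coronal, 95
sagittal and 120 axial slices at 0.5 mm, i.e. roughly 107 cm^3 — the scale of
a healthy adult tongue.  Atrophy is modelled by a multiplicative factor on all
semi-axes (``volume_scale``), so true volume scales with its cube.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .volume import CANONICAL_AXES, LabeledVolume

__all__ = [
    "PhantomSpec",
    "GroupSpec",
    "CohortSpec",
    "CohortSubject",
    "generate_phantom",
    "generate_cohort",
    "save_cohort",
]

#: default semi-axes (AP, LR, IS) in mm; 4/3*pi*abc ~ 106.7 cm^3
DEFAULT_SEMIAXES_MM: tuple[float, float, float] = (35.75, 23.75, 30.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a single synthetic subject.

    ``deform_amplitude`` scales a smooth, seeded, low-order angular
    perturbation of the ellipsoid boundary radius (degree-2 spherical
    harmonics), emulating inter-subject shape variation without anatomical
    modelling.  Intensities are arbitrary MR-like units; downstream z-score
    normalization removes their scale.  Noise is additive Gaussian.
    """

    grid_shape: int = 256
    spacing_mm: float = 0.5
    tongue_semiaxes_mm: tuple[float, float, float] = DEFAULT_SEMIAXES_MM
    deform_amplitude: float = 0.05
    tongue_intensity: float = 100.0
    background_intensity: float = 20.0
    distractor_intensity: float = 85.0
    noise_sigma: float = 10.0
    volume_scale: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.grid_shape < 8:
            raise ValueError("grid_shape too small")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        if any(a <= 0 for a in self.tongue_semiaxes_mm):
            raise ValueError("tongue semi-axes must be strictly positive")
        if self.volume_scale <= 0:
            raise ValueError("volume_scale must be strictly positive (degenerate tongue)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.deform_amplitude < 0:
            raise ValueError("deform_amplitude must be >= 0")
        half_extent = self.grid_shape * self.spacing_mm / 2.0
        # conservative bound: deformed radius <= (1 + 2*amplitude) * semi-axis
        margin = (1.0 + 2.0 * self.deform_amplitude) * self.volume_scale
        if any(margin * a + self.spacing_mm > half_extent for a in self.tongue_semiaxes_mm):
            raise ValueError(
                "scaled tongue does not fit inside the grid "
                f"(half extent {half_extent:.1f} mm)"
            )

    @property
    def analytic_volume_cm3(self) -> float:
        """Volume of the *undeformed* scaled ellipsoid, 4/3*pi*abc, in cm^3."""
        a, b, c = (self.volume_scale * s for s in self.tongue_semiaxes_mm)
        return float(4.0 / 3.0 * np.pi * a * b * c / 1000.0)


def _deformation(nx: np.ndarray, ny: np.ndarray, nz: np.ndarray,
                 coeffs: np.ndarray, amplitude: float) -> np.ndarray:
    """Smooth degree-2 angular perturbation evaluated at unit directions.

    Resolution-independent by construction (a function of direction only), so
    the voxelized mask converges to a well-defined continuum shape as the
    grid is refined.
    """
    basis = (
        coeffs[0] * nx * ny
        + coeffs[1] * ny * nz
        + coeffs[2] * nx * nz
        + coeffs[3] * (nx * nx - ny * ny)
        + coeffs[4] * (ny * ny - nz * nz)
    )
    return amplitude * basis / np.sqrt(len(coeffs))


def _physical_coords(n: int, spacing: float) -> np.ndarray:
    return ((np.arange(n) - (n - 1) / 2.0) * spacing).astype(np.float32)


def generate_phantom(spec: PhantomSpec) -> LabeledVolume:
    """Generate one synthetic subject; bit-deterministic for a fixed seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    coeffs = rng.standard_normal(5)

    n = spec.grid_shape
    c = _physical_coords(n, spec.spacing_mm)
    xx = c[:, None, None]
    yy = c[None, :, None]
    zz = c[None, None, :]
    r2 = xx**2 + yy**2 + zz**2
    r = np.sqrt(r2)
    r_safe = np.where(r > 0, r, 1.0)

    semi = np.asarray(spec.tongue_semiaxes_mm, dtype=np.float64) * spec.volume_scale
    rho = np.sqrt((xx / semi[0]) ** 2 + (yy / semi[1]) ** 2 + (zz / semi[2]) ** 2)
    d = _deformation(xx / r_safe, yy / r_safe, zz / r_safe, coeffs, spec.deform_amplitude)
    mask = (rho <= 1.0 + d).astype(np.uint8)

    # reject a tongue clipped by the grid (exact check on the voxelized mask)
    if (
        mask[0].any() or mask[-1].any()
        or mask[:, 0].any() or mask[:, -1].any()
        or mask[..., 0].any() or mask[..., -1].any()
    ):
        raise ValueError("tongue exceeds grid: mask touches the volume boundary")

    # distractor blobs: 2-4 ellipsoids abutting (never overlapping) the tongue
    distractors = np.zeros_like(mask, dtype=bool)
    n_blobs = int(rng.integers(2, 5))
    half_extent = n * spec.spacing_mm / 2.0
    for _ in range(n_blobs):
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v)
        frac = rng.uniform(0.25, 0.45)
        bsemi = frac * semi
        d_v = _deformation(v[0], v[1], v[2], coeffs, spec.deform_amplitude)
        r_tongue = (1.0 + d_v) / np.sqrt(np.sum((v / semi) ** 2))
        r_blob = 1.0 / np.sqrt(np.sum((v / bsemi) ** 2))
        center = v * (r_tongue + r_blob + spec.spacing_mm)
        if np.any(np.abs(center) + bsemi > half_extent - spec.spacing_mm):
            continue  # would be clipped; skip this blob
        blob = (
            ((xx - center[0]) / bsemi[0]) ** 2
            + ((yy - center[1]) / bsemi[1]) ** 2
            + ((zz - center[2]) / bsemi[2]) ** 2
        ) <= 1.0
        distractors |= blob
    distractors &= mask == 0

    bg = spec.background_intensity
    tissue = np.full(mask.shape, bg, dtype=np.float32)
    tissue[mask == 1] = spec.tongue_intensity
    tissue[distractors] = spec.distractor_intensity
    # soft tissue boundaries: ~1 voxel partial-volume blur
    tissue = gaussian_filter(tissue, sigma=0.8)
    intensity = tissue + rng.normal(0.0, spec.noise_sigma, size=tissue.shape)

    return LabeledVolume(
        intensity=intensity.astype(np.float32),
        mask=mask,
        spacing_mm=(spec.spacing_mm,) * 3,
        axis_labels=CANONICAL_AXES,
    )


# --------------------------------------------------------------------- cohort


@dataclass(frozen=True)
class GroupSpec:
    """One study arm: subject count and the tongue-size distribution."""

    n_subjects: int
    scale_mean: float
    scale_sd: float

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("each group needs n_subjects >= 2")
        if self.scale_mean <= 0:
            raise ValueError("scale_mean must be positive")
        if self.scale_sd < 0:
            raise ValueError("scale_sd must be >= 0")


def _default_groups() -> dict[str, GroupSpec]:
    # Healthy tongue ~106 cm^3 (sd 8); atrophic arm scaled so mean volume is
    # ~14% smaller (91 cm^3, sd 16).  Volume ~ scale^3, so sd_scale ~ cv/3.
    atrophic_mean = (91.0 / 106.0) ** (1.0 / 3.0)
    return {
        "control": GroupSpec(19, 1.0, 8.0 / 106.0 / 3.0),
        "atrophic": GroupSpec(19, atrophic_mean, atrophic_mean * 16.0 / 91.0 / 3.0),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Two-arm (or k-arm) cohort built from a shared phantom template.

    Per-subject seeds and size draws depend only on the master seed and the
    subject index within the group, so two groups with identical scale
    distributions produce pairwise-matched subjects.
    """

    groups: dict[str, GroupSpec] = field(default_factory=_default_groups)
    template: PhantomSpec = field(default_factory=PhantomSpec)
    master_seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("cohort needs at least one group")
        for g in self.groups.values():
            g.validate()


@dataclass
class CohortSubject:
    subject_id: str
    group: str
    seed: int
    volume_scale: float
    volume: LabeledVolume

    @property
    def true_volume_cm3(self) -> float:
        return float(self.volume.mask.sum()) * self.volume.voxel_volume_mm3 / 1000.0


def generate_cohort(cohort: CohortSpec) -> tuple[list[CohortSubject], pd.DataFrame]:
    """Generate all subjects plus a manifest of every drawn parameter."""
    cohort.validate()
    subjects: list[CohortSubject] = []
    rows = []
    for group_name, group in cohort.groups.items():
        for i in range(group.n_subjects):
            ss = np.random.SeedSequence([cohort.master_seed, i])
            seed = int(ss.generate_state(1)[0] % (2**31))
            rng = np.random.default_rng(np.random.SeedSequence([cohort.master_seed, i, 1]))
            scale = group.scale_mean + group.scale_sd * float(rng.standard_normal())
            scale = max(scale, 0.05 * group.scale_mean)  # guard absurd tail draws
            spec = replace(cohort.template, volume_scale=scale, seed=seed)
            vol = generate_phantom(spec)
            subj = CohortSubject(
                subject_id=f"{group_name}_{i:03d}",
                group=group_name,
                seed=seed,
                volume_scale=scale,
                volume=vol,
            )
            subjects.append(subj)
            rows.append(
                {
                    "subject_id": subj.subject_id,
                    "group": group_name,
                    "seed": seed,
                    "volume_scale": scale,
                    "true_volume_cm3": subj.true_volume_cm3,
                }
            )
    return subjects, pd.DataFrame(rows)


def save_cohort(subjects: list[CohortSubject], manifest: pd.DataFrame, outdir: str | Path) -> None:
    """Write NIfTI intensity/mask pairs and the manifest CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in subjects:
        s.volume.save(
            outdir / f"{s.subject_id}.nii.gz",
            outdir / f"{s.subject_id}_mask.nii.gz",
        )
    manifest.to_csv(outdir / "manifest.csv", index=False)
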