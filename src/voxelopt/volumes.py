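"""Synthetic aging-brain cohorts and NIfTI volume I/O.

This module stands in for the upstream voxel-based-morphometry pipeline
(segmentation + nonlinear normalization), which is out of scope: the rest of
the package consumes already-normalized gray-matter maps, one 3-D volume per
subject on a shared grid.  The generator plants a smooth "atrophy template" —
a set of loci whose intensity declines linearly with age — on top of
spatially correlated noise, so that downstream prediction accuracy depends
measurably on the resampling voxel size and the smoothing kernel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import FormatError, InputError, ParameterError

__all__ = [
    "VolumeGrid",
    "SubjectRecord",
    "CohortSpec",
    "generate_atrophy_template",
    "synthesize_subject",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "read_nifti",
    "write_nifti",
    "template_weighted_mean",
]

#: Default number of Gaussian bumps composing the atrophy template.
DEFAULT_N_BUMPS = 12


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D scalar field with voxel spacing in mm.

    The unit of all image math in this package.  Intensities are unitless
    (gray-matter probability/volume style, nominally in [0, 1] for generated
    cohorts) and must be finite.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3 or min(data.shape) < 1:
            raise ParameterError(f"volume must be 3-D with all dims >= 1, got shape {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ParameterError("volume intensities must be finite")
        spacing = tuple(float(s) for s in np.atleast_1d(self.spacing_mm).ravel())
        if len(spacing) == 1:
            spacing = spacing * 3
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ParameterError(f"spacing must be 3 positive lengths in mm, got {self.spacing_mm}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing_mm", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical edge lengths of the field of view."""
        return tuple(n * s for n, s in zip(self.data.shape, self.spacing_mm))


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: id, chronological age, optional group label, volume."""

    id: str
    age_years: float
    group: Optional[str] = None
    volume: Union[VolumeGrid, str, Path, None] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.age_years) or self.age_years <= 0:
            raise ParameterError(f"age must be a positive real, got {self.age_years}")

    def load_volume(self) -> VolumeGrid:
        """Return the in-memory volume, reading from disk if needed."""
        if isinstance(self.volume, VolumeGrid):
            return self.volume
        if self.volume is None:
            raise InputError(f"subject {self.id} carries no volume")
        return read_nifti(self.volume)


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to synthesize a cohort deterministically.

    Parameters
    ----------
    effect_size
        Absolute intensity loss per decade of age at full-weight template
        loci (unitless intensity per 10 years).
    signal_scale_mm
        Characteristic spatial scale of the planted age signal: the 1/e
        autocorrelation distance of the template field.
    noise_sd
        Standard deviation of the additive spatially correlated noise.
    noise_corr_mm
        Gaussian correlation length (filter sd, mm) of the noise field;
        0 gives white noise.
    anat_sd, anat_corr_mm
        A second, coarse-scale noise component emulating smooth
        between-subject anatomical variability; unlike the fine scan/
        registration noise it is not removable by smoothing, so it
        penalizes over-smoothed or over-coarsened pre-processing.
    baseline_intensity
        Intensity of template-free tissue before decline and noise.
    """

    n_subjects: int = 400
    age_range_years: tuple[float, float] = (16.0, 90.0)
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    native_spacing_mm: float = 2.0
    effect_size: float = 0.04
    signal_scale_mm: float = 8.0
    noise_sd: float = 0.30
    noise_corr_mm: float = 1.0
    anat_sd: float = 0.08
    anat_corr_mm: float = 16.0
    baseline_intensity: float = 0.5
    n_bumps: int = DEFAULT_N_BUMPS
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.age_range_years
        if not lo < hi:
            raise ParameterError(f"age range must satisfy lo < hi, got {self.age_range_years}")
        if self.n_subjects < 2:
            raise ParameterError("a cohort needs at least 2 subjects")
        if self.effect_size < 0:
            raise ParameterError("effect_size must be >= 0")
        if self.signal_scale_mm <= 0 or self.native_spacing_mm <= 0:
            raise ParameterError("signal scale and native spacing must be positive")
        if self.noise_sd < 0 or self.noise_corr_mm < 0:
            raise ParameterError("noise parameters must be nonnegative")
        if self.anat_sd < 0 or self.anat_corr_mm < 0:
            raise ParameterError("anatomical-variability parameters must be nonnegative")


def generate_atrophy_template(
    grid_shape: Sequence[int],
    native_spacing_mm: float,
    signal_scale_mm: float,
    seed: int,
    n_bumps: int = DEFAULT_N_BUMPS,
) -> VolumeGrid:
    """Build the nonnegative weight map of age-sensitive loci.

    The template is a sum of ``n_bumps`` isotropic Gaussian bumps at seeded
    pseudo-anatomical positions, normalized to a maximum of 1.  The bump sd
    is ``signal_scale_mm / 2``, which makes the field's theoretical
    autocorrelation Gaussian with a 1/e distance of exactly
    ``signal_scale_mm`` (the convolution of two Gaussians of sd s/2 has sd
    s/sqrt(2), and exp(-h^2 / (2 (s/sqrt2)^2)) = 1/e at h = s).

    Deterministic for a fixed seed.
    """
    shape = tuple(int(n) for n in grid_shape)
    if len(shape) != 3 or min(shape) < 4:
        raise ParameterError(f"grid shape must be 3 dims of at least 4 voxels, got {grid_shape}")
    if signal_scale_mm <= 0:
        raise ParameterError("signal_scale_mm must be positive")
    if native_spacing_mm <= 0:
        raise ParameterError("native_spacing_mm must be positive")
    if signal_scale_mm < native_spacing_mm:
        raise ParameterError(
            f"signal scale {signal_scale_mm} mm is below the voxel edge "
            f"{native_spacing_mm} mm: a sub-voxel signal is unrepresentable"
        )
    if n_bumps < 1:
        raise ParameterError("need at least one template bump")

    rng = np.random.default_rng(seed)
    sigma = signal_scale_mm / 2.0
    extent = np.array(shape, dtype=float) * native_spacing_mm
    margin = np.minimum(sigma, extent / 4.0)
    centers = rng.uniform(margin, extent - margin, size=(n_bumps, 3))

    # voxel-center physical coordinates per axis
    axes = [(np.arange(n) + 0.5) * native_spacing_mm for n in shape]
    field = np.zeros(shape, dtype=np.float64)
    for cx, cy, cz in centers:
        gx = np.exp(-((axes[0] - cx) ** 2) / (2 * sigma**2))
        gy = np.exp(-((axes[1] - cy) ** 2) / (2 * sigma**2))
        gz = np.exp(-((axes[2] - cz) ** 2) / (2 * sigma**2))
        field += gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
    field /= field.max()
    return VolumeGrid(field, (native_spacing_mm,) * 3)


def _correlated_noise(
    shape: tuple[int, int, int],
    spacing_mm: float,
    noise_sd: float,
    noise_corr_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """White noise convolved with a Gaussian of sd ``noise_corr_mm``,
    re-standardized to sd ``noise_sd``."""
    white = rng.standard_normal(shape)
    if noise_corr_mm > 0:
        field = gaussian_filter(white, sigma=noise_corr_mm / spacing_mm, mode="reflect")
    else:
        field = white
    sd = field.std()
    if sd == 0:  # pragma: no cover - only for degenerate single-voxel grids
        return np.zeros(shape)
    return field * (noise_sd / sd)


def synthesize_subject(
    age_years: float,
    template: VolumeGrid,
    spec: CohortSpec,
    rng: np.random.Generator,
    subject_id: str = "sub-0000",
    group: Optional[str] = None,
) -> SubjectRecord:
    """Synthesize one subject's gray-matter map at the given age.

    intensity = baseline − effect_size · (age / 10) · template + noise,
    clipped to [0, 1].  Noise is Gaussian with sd ``spec.noise_sd`` and
    correlation length ``spec.noise_corr_mm``.
    """
    lo, hi = spec.age_range_years
    if not (lo <= age_years <= hi):
        raise ParameterError(f"age {age_years} outside cohort range {spec.age_range_years}")
    data = spec.baseline_intensity - spec.effect_size * (age_years / 10.0) * template.data
    if spec.noise_sd > 0:
        data = data + _correlated_noise(
            template.shape, template.spacing_mm[0], spec.noise_sd, spec.noise_corr_mm, rng
        )
    if spec.anat_sd > 0:
        data = data + _correlated_noise(
            template.shape, template.spacing_mm[0], spec.anat_sd, spec.anat_corr_mm, rng
        )
    data = np.clip(data, 0.0, 1.0)
    return SubjectRecord(
        id=subject_id,
        age_years=float(age_years),
        group=group,
        volume=VolumeGrid(data, template.spacing_mm),
    )


def generate_cohort(
    spec: CohortSpec,
    design: str = "uniform",
    young_range: tuple[float, float] = (16.0, 22.0),
    old_range: tuple[float, float] = (51.0, 90.0),
) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Generate a full synthetic cohort plus its subject table.

    ``design='uniform'`` draws ages uniformly over ``spec.age_range_years``
    (regression-style cohorts); ``design='two_group'`` draws two equal age
    blocks labelled young/old (classification-style cohorts, mirroring a
    young 16-22 vs old 51-90 split).  Entirely deterministic in ``spec``.
    """
    if design not in ("uniform", "two_group"):
        raise InputError(f"unknown cohort design {design!r}")
    rng = np.random.default_rng(spec.seed)
    template = generate_atrophy_template(
        spec.grid_shape, spec.native_spacing_mm, spec.signal_scale_mm, spec.seed, spec.n_bumps
    )
    lo, hi = spec.age_range_years

    if design == "uniform":
        ages = rng.uniform(lo, hi, size=spec.n_subjects)
        groups: list[Optional[str]] = [None] * spec.n_subjects
    else:
        n_young = spec.n_subjects // 2
        n_old = spec.n_subjects - n_young
        y_lo, y_hi = max(young_range[0], lo), min(young_range[1], hi)
        o_lo, o_hi = max(old_range[0], lo), min(old_range[1], hi)
        ages = np.concatenate(
            [rng.uniform(y_lo, y_hi, size=n_young), rng.uniform(o_lo, o_hi, size=n_old)]
        )
        groups = ["young"] * n_young + ["old"] * n_old

    width = len(str(spec.n_subjects))
    subjects = [
        synthesize_subject(
            age, template, spec, rng, subject_id=f"sub-{i:0{width}d}", group=groups[i]
        )
        for i, age in enumerate(ages)
    ]
    table = pd.DataFrame(
        {
            "id": [s.id for s in subjects],
            "age": [s.age_years for s in subjects],
            "group": [s.group if s.group is not None else "" for s in subjects],
        }
    )
    return subjects, table


def template_weighted_mean(volume: VolumeGrid, template: VolumeGrid) -> float:
    """Mean intensity weighted by the atrophy template — the scalar summary
    the planted age signal acts on."""
    w = template.data
    return float(np.sum(volume.data * w) / np.sum(w))


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_nifti(path: Union[str, Path]) -> VolumeGrid:
    """Read a NIfTI volume; only the voxel spacing is consumed from the
    header (orientation handling is out of scope)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        zooms = img.header.get_zooms()[:3]
    except (nib.filebasedimages.ImageFileError, OSError, ValueError) as exc:
        raise FormatError(f"{path} is not a readable NIfTI volume: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return VolumeGrid(data, tuple(float(z) for z in zooms))


def write_nifti(volume: VolumeGrid, path: Union[str, Path]) -> Path:
    """Write a volume as NIfTI-1 with identity rotation and the spacing on
    the affine diagonal; data stored as float32."""
    path = Path(path)
    affine = np.diag(list(volume.spacing_mm) + [1.0])
    img = nib.Nifti1Image(volume.data.astype(np.float32), affine)
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))
    return path


def write_cohort(
    subjects: Sequence[SubjectRecord], table: pd.DataFrame, out_dir: Union[str, Path]
) -> Path:
    """Write one .nii.gz per subject plus ``subjects.csv`` (id,age,group)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for s in subjects:
        write_nifti(s.load_volume(), out_dir / f"{s.id}.nii.gz")
    table.to_csv(out_dir / "subjects.csv", index=False)
    return out_dir


def read_cohort(cohort_dir: Union[str, Path], load_volumes: bool = True) -> list[SubjectRecord]:
    """Read a cohort written by :func:`write_cohort`."""
    cohort_dir = Path(cohort_dir)
    table = pd.read_csv(cohort_dir / "subjects.csv", dtype={"id": str}, keep_default_na=False)
    subjects = []
    for row in table.itertuples(index=False):
        path = cohort_dir / f"{row.id}.nii.gz"
        vol: Union[VolumeGrid, Path] = read_nifti(path) if load_volumes else path
        group = row.group if getattr(row, "group", "") else None
        subjects.append(SubjectRecord(id=row.id, age_years=float(row.age), group=group, volume=vol))
    return subjects
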