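"""The optimized pre-processing stage: resample → smooth → vectorize.

These are the two tunable operations the Bayesian optimizer searches over:
the isotropic target voxel size of the resampling step and the FWHM of the
Gaussian smoothing kernel.  Order is fixed (resample, then smooth, then
vectorize); the smoothing FWHM is interpreted in mm at the resampled
resolution, so the kernel sd in voxels depends on the candidate voxel size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .errors import InputError, ParameterError
from .volumes import SubjectRecord, VolumeGrid

__all__ = [
    "PreprocParams",
    "FeatureMatrix",
    "fwhm_to_sigma",
    "resample_isotropic",
    "smooth_fwhm",
    "vectorize_dataset",
]

#: Anti-alias pre-filter sd, in source voxels per unit downsampling factor.
ANTIALIAS_SD_PER_FACTOR = 0.42


@dataclass(frozen=True)
class PreprocParams:
    """The optimized pair: isotropic voxel edge length and smoothing FWHM,
    both in mm.  This is the point in the 2-D search space."""

    voxel_size_mm: float
    fwhm_mm: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.voxel_size_mm) and self.voxel_size_mm > 0):
            raise ParameterError(f"voxel size must be positive, got {self.voxel_size_mm}")
        if not (np.isfinite(self.fwhm_mm) and self.fwhm_mm > 0):
            raise ParameterError(f"FWHM must be positive, got {self.fwhm_mm}")

    def as_array(self) -> np.ndarray:
        return np.array([self.voxel_size_mm, self.fwhm_mm], dtype=float)


@dataclass(frozen=True)
class FeatureMatrix:
    """Vectorized intensities: one row per subject, one column per retained
    voxel of the resampled grid (raster / C order)."""

    values: np.ndarray
    feature_index: np.ndarray  # flat voxel index in the resampled grid, per column
    subject_ids: tuple[str, ...]
    grid_shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise InputError("feature matrix contains non-finite entries")
        if self.values.shape[1] != len(self.feature_index):
            raise InputError("feature_index length must equal the column count")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def voxel_coordinates(self) -> np.ndarray:
        """(n_features, 3) integer voxel coordinates for each column."""
        return np.stack(np.unravel_index(self.feature_index, self.grid_shape), axis=1)

    def to_ascii(self, path) -> None:
        """Plain-text export: one whitespace-separated row per subject."""
        np.savetxt(path, self.values, fmt="%.8g")


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Gaussian sd from full-width at half-maximum: FWHM = 2·sqrt(2 ln 2)·σ."""
    if not (np.isfinite(fwhm_mm) and fwhm_mm > 0):
        raise ParameterError(f"FWHM must be positive, got {fwhm_mm}")
    return fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def resample_isotropic(
    volume: VolumeGrid, target_voxel_mm: float, mode: str = "linear"
) -> VolumeGrid:
    """Resample a volume to an isotropic target voxel size.

    ``mode='linear'`` (default) is trilinear interpolation at the new voxel
    centers with a Gaussian anti-alias pre-filter
    (sd = 0.42 × downsampling factor, in source voxels) on any axis being
    downsampled.  ``mode='block'`` averages non-overlapping blocks and
    requires the target to be an integer multiple of an isotropic source
    spacing.  Output shape is ceil(shape · source_spacing / target) per
    axis; a target equal to the source spacing returns the input unchanged.
    """
    if not (np.isfinite(target_voxel_mm) and target_voxel_mm > 0):
        raise ParameterError(f"target voxel size must be positive, got {target_voxel_mm}")
    src = np.asarray(volume.spacing_mm, dtype=float)
    if np.allclose(src, target_voxel_mm, rtol=0, atol=1e-12):
        return volume
    if target_voxel_mm < 0.5 * src.min():
        warnings.warn(
            f"target {target_voxel_mm} mm is below half the source spacing "
            f"{tuple(src)}: upsampling adds no information",
            stacklevel=2,
        )

    if mode == "block":
        if not np.allclose(src, src[0]):
            raise ParameterError("block mode requires isotropic source spacing")
        factor = target_voxel_mm / src[0]
        if abs(factor - round(factor)) > 1e-9:
            raise ParameterError("block mode requires an integer downsampling factor")
        f = int(round(factor))
        shape = volume.data.shape
        if any(n % f for n in shape):
            raise ParameterError(f"shape {shape} not divisible by block factor {f}")
        out = (
            volume.data.reshape(shape[0] // f, f, shape[1] // f, f, shape[2] // f, f)
            .mean(axis=(1, 3, 5))
        )
        return VolumeGrid(out, (target_voxel_mm,) * 3)
    if mode != "linear":
        raise ParameterError(f"unknown resampling mode {mode!r}")

    factors = target_voxel_mm / src
    sigmas = np.where(factors > 1.0, ANTIALIAS_SD_PER_FACTOR * factors, 0.0)
    data = volume.data
    if np.any(sigmas > 0):
        data = gaussian_filter(data, sigma=sigmas, mode="reflect")

    out_shape = tuple(int(math.ceil(n * s / target_voxel_mm)) for n, s in zip(data.shape, src))
    # voxel-center alignment: output center (j + 0.5)·t maps to source index
    # ((j + 0.5)·t / s) − 0.5
    coords = np.meshgrid(
        *[
            (np.arange(m) + 0.5) * target_voxel_mm / s - 0.5
            for m, s in zip(out_shape, src)
        ],
        indexing="ij",
    )
    out = map_coordinates(data, coords, order=1, mode="nearest")
    return VolumeGrid(out, (target_voxel_mm,) * 3)


def smooth_fwhm(volume: VolumeGrid, fwhm_mm: float) -> VolumeGrid:
    """Separable Gaussian smoothing with the kernel specified as FWHM in mm.

    Reflective boundaries preserve the global mean; the per-axis sd in
    voxels is fwhm_to_sigma(fwhm) / spacing.
    """
    sigma_mm = fwhm_to_sigma(fwhm_mm)
    sigmas = [sigma_mm / s for s in volume.spacing_mm]
    out = gaussian_filter(volume.data, sigma=sigmas, mode="reflect")
    return VolumeGrid(out, volume.spacing_mm)


def preprocess_volume(
    volume: VolumeGrid, params: PreprocParams, resample_mode: str = "linear"
) -> VolumeGrid:
    """Apply the full optimized stage to one volume: resample then smooth."""
    return smooth_fwhm(resample_isotropic(volume, params.voxel_size_mm, resample_mode), params.fwhm_mm)


def vectorize_dataset(
    subjects: Sequence[SubjectRecord],
    params: PreprocParams,
    resample_mode: str = "linear",
    mask: Optional[np.ndarray] = None,
) -> FeatureMatrix:
    """Pre-process every subject and stack flattened intensities.

    All subjects must share one grid.  Voxels that are exactly zero in every
    subject are dropped (implicit mask); alternatively an explicit boolean
    ``mask`` over the resampled grid may be supplied.  Row order follows the
    input order.
    """
    if len(subjects) == 0:
        raise InputError("empty subject list")
    volumes = [s.load_volume() for s in subjects]
    shapes = {v.shape for v in volumes}
    spacings = {v.spacing_mm for v in volumes}
    if len(shapes) != 1 or len(spacings) != 1:
        raise InputError(f"subjects must share one grid, found shapes {shapes}, spacings {spacings}")

    rows = []
    out_shape: tuple[int, int, int] = ()
    out_spacing: tuple[float, float, float] = ()
    for v in volumes:
        pv = preprocess_volume(v, params, resample_mode)
        out_shape, out_spacing = pv.shape, pv.spacing_mm
        rows.append(pv.data.ravel(order="C"))
    values = np.stack(rows, axis=0)

    if mask is not None:
        keep = np.asarray(mask, dtype=bool).ravel(order="C")
        if keep.size != values.shape[1]:
            raise InputError("explicit mask does not match the resampled grid")
    else:
        keep = np.any(values != 0.0, axis=0)
    feature_index = np.flatnonzero(keep)
    return FeatureMatrix(
        values=values[:, keep],
        feature_index=feature_index,
        subject_ids=tuple(s.id for s in subjects),
        grid_shape=out_shape,
        spacing_mm=out_spacing,
    )
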