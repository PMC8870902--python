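"""Preprocessing of two-photon stacks before surface extraction.

Three steps produce a clean, cell-free gel volume plus a validity mask:

1. linear spectral unmixing of gel/cell channel crosstalk
   ("color deconvolution"): per-voxel inversion of a 2x2 mixing matrix;
2. bright-outlier removal (ImageJ "Remove Outliers" semantics: replace a
   pixel by the median of a circular neighbourhood when it exceeds that
   median by more than a threshold), applied slice by slice in (y, x);
3. a validity mask excluding low-SNR regions near the image edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .errors import EmptyMaskError, SingularMatrixError
from .stack_io import CELL, GEL, MultiChannelStack

_DET_TOL = 1e-12


@dataclass(frozen=True)
class MixingMatrix:
    """2x2 matrix mapping true (gel, cell) intensities to observed ones.

    ``observed = m @ true`` per voxel. Must be invertible with positive
    diagonal entries (each fluorophore detected mostly in its own channel).
    """

    m: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 0.0), (0.0, 1.0))

    def __post_init__(self) -> None:
        arr = self.as_array()
        if arr.shape != (2, 2) or not np.all(np.isfinite(arr)):
            raise SingularMatrixError(f"mixing matrix must be a finite 2x2 matrix, got {arr!r}")
        if abs(np.linalg.det(arr)) <= _DET_TOL:
            raise SingularMatrixError(f"mixing matrix is singular: det={np.linalg.det(arr)}")
        if arr[0, 0] <= 0 or arr[1, 1] <= 0:
            raise SingularMatrixError("mixing matrix diagonal entries must be positive")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.m, dtype=float)

    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.as_array())

    @property
    def is_identity(self) -> bool:
        return np.array_equal(self.as_array(), np.eye(2))


@dataclass
class ValidityMask:
    """2-D boolean mask of pixels included in the analysis."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise EmptyMaskError(f"validity mask must be 2-D, got shape {self.mask.shape}")

    @property
    def any_valid(self) -> bool:
        return bool(self.mask.any())

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())


def unmix_channels(stack: MultiChannelStack, mix: MixingMatrix) -> MultiChannelStack:
    """Invert linear channel crosstalk on the gel/cell channel pair.

    At every voxel the observed (gel, cell) vector is multiplied by the
    inverse mixing matrix and clipped at zero. Geometry, roles, and any
    additional channels are unchanged. The identity matrix is a no-op.
    """
    gel_name = stack.channel_roles[GEL]
    cell_name = stack.channel_roles[CELL]
    if mix.is_identity:
        channels = {name: arr.copy() for name, arr in stack.channels.items()}
        return MultiChannelStack(stack.geometry, channels, dict(stack.channel_roles))
    inv = mix.inverse()
    obs_g = np.asarray(stack.channels[gel_name], dtype=np.float64)
    obs_c = np.asarray(stack.channels[cell_name], dtype=np.float64)
    true_g = inv[0, 0] * obs_g + inv[0, 1] * obs_c
    true_c = inv[1, 0] * obs_g + inv[1, 1] * obs_c
    channels = {name: arr.copy() for name, arr in stack.channels.items()}
    channels[gel_name] = np.clip(true_g, 0.0, None)
    channels[cell_name] = np.clip(true_c, 0.0, None)
    return MultiChannelStack(stack.geometry, channels, dict(stack.channel_roles))


def forward_mix(stack: MultiChannelStack, mix: MixingMatrix) -> MultiChannelStack:
    """Apply crosstalk forward (observed = m @ true); phantom forward model."""
    gel_name = stack.channel_roles[GEL]
    cell_name = stack.channel_roles[CELL]
    m = mix.as_array()
    # preserve the input float dtype (the phantom renders in float32)
    dtype = np.result_type(stack.channels[gel_name].dtype, np.float32)
    true_g = np.asarray(stack.channels[gel_name], dtype=dtype)
    true_c = np.asarray(stack.channels[cell_name], dtype=dtype)
    channels = {name: arr.copy() for name, arr in stack.channels.items()}
    channels[gel_name] = np.clip(m[0, 0] * true_g + m[0, 1] * true_c, 0.0, None)
    channels[cell_name] = np.clip(m[1, 0] * true_g + m[1, 1] * true_c, 0.0, None)
    return MultiChannelStack(stack.geometry, channels, dict(stack.channel_roles))


def remove_outliers(volume: np.ndarray, radius_px: int = 2, threshold: float = 50.0) -> np.ndarray:
    """Remove small bright artifacts by a median test (bright variant).

    Slice by slice in (y, x): each pixel is compared with the median over
    the disk of ``radius_px``; if ``pixel - median > threshold`` the pixel
    is replaced by that median, otherwise kept. Edges use edge replication.
    Never increases any pixel value; isolated speckles vanish in one pass
    (clusters of adjacent outliers can need repeated application).
    """
    if radius_px < 1:
        raise ValueError(f"radius_px must be >= 1, got {radius_px}")
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    vol = np.asarray(volume)
    squeeze = False
    if vol.ndim == 2:
        vol = vol[np.newaxis]
        squeeze = True
    if vol.ndim != 3:
        raise ValueError(f"expected a 2-D slice or 3-D volume, got ndim={vol.ndim}")
    footprint = disk(radius_px)[np.newaxis]  # per-slice circular neighbourhood
    med = ndimage.median_filter(vol, footprint=footprint, mode="nearest")
    out = np.where(vol - med > threshold, med, vol)
    return out[0] if squeeze else out


def make_validity_mask(
    gel_volume: np.ndarray, snr_floor: float = 3.0, erode_border_px: int = 8
) -> ValidityMask:
    """Mask out low-SNR pixels and a border margin.

    A pixel column (y, x) is valid iff its maximum gel intensity over z,
    divided by a robust noise scale of the volume (1.4826 x median absolute
    deviation of all voxel intensities), reaches ``snr_floor``. The valid
    region is then cleared within ``erode_border_px`` of the image border
    and morphologically eroded with a disk of that radius.
    """
    if snr_floor < 0:
        raise ValueError(f"snr_floor must be >= 0, got {snr_floor}")
    if erode_border_px < 0:
        raise ValueError(f"erode_border_px must be >= 0, got {erode_border_px}")
    vol = np.asarray(gel_volume)
    if vol.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got ndim={vol.ndim}")
    if not np.issubdtype(vol.dtype, np.floating):
        vol = vol.astype(np.float32)
    proj = vol.max(axis=0)
    med = np.median(vol)
    noise = 1.4826 * float(np.median(np.abs(vol - vol.dtype.type(med))))
    if noise == 0:
        # noiseless volume: any nonzero signal counts as infinite SNR
        mask = proj > 0 if snr_floor > 0 else np.ones_like(proj, dtype=bool)
    else:
        mask = proj / noise >= snr_floor
    if erode_border_px > 0:
        border = np.zeros_like(mask)
        b = erode_border_px
        border[b:-b or None, b:-b or None] = True
        mask &= border
        mask = ndimage.binary_erosion(mask, structure=disk(erode_border_px))
    if not mask.any():
        raise EmptyMaskError("validity mask is entirely false; input unusable")
    return ValidityMask(mask)
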