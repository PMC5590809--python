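"""Geometric and gray-level normalization of tumor volumes.

All volumes are voxel-indexed, 0-based, axis order ``(z, y, x)``; this is the
single place where that convention is defined.  ``spacing_mm`` follows the same
axis order.  Intensities are arbitrary real units (HU for CT); texture matrices
operate on the discretized gray-level alphabet produced by :func:`discretize`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


class EmptyMaskError(ValueError):
    """Raised when an operation requires at least one masked voxel."""


@dataclass
class VolumeWithMask:
    """A 3D intensity grid with a binary region-of-interest mask.

    Parameters
    ----------
    intensities : ndarray, shape (nz, ny, nx)
        Real-valued intensity grid.
    mask : ndarray of bool, same shape
        True inside the tumor region.
    spacing_mm : tuple of 3 floats
        Physical voxel size along (z, y, x), strictly positive.
    origin_mm : tuple of 3 floats
        Physical coordinate of voxel (0, 0, 0).
    """

    intensities: np.ndarray
    mask: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if self.intensities.shape != self.mask.shape:
            raise ValueError("intensities and mask dimensions differ")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be 3 positive lengths")
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    def masked_values(self) -> np.ndarray:
        """Intensities of masked voxels, flattened in C order."""
        return self.intensities[self.mask]

    def require_nonempty(self) -> None:
        if self.n_masked == 0:
            raise EmptyMaskError("mask has no voxels")


@dataclass
class GrayVolume:
    """A volume discretized to a positive-integer gray-level alphabet.

    ``levels`` is 0 outside the mask and in ``1..n_levels`` inside;
    ``n_levels`` equals the maximum observed level so the alphabet carries
    no empty top bins.
    """

    levels: np.ndarray
    n_levels: int
    bin_width: float
    mask: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels)
        self.mask = np.asarray(self.mask, dtype=bool)
        inside = self.levels[self.mask]
        if inside.size and (inside.min() < 1 or inside.max() != self.n_levels):
            raise ValueError("levels inside mask must span 1..n_levels")


def resample(
    v: VolumeWithMask, target_spacing: tuple[float, float, float]
) -> VolumeWithMask:
    """Resample a volume (and its mask) to a new voxel spacing.

    Intensities are interpolated trilinearly, the mask with linear
    interpolation thresholded at 0.5 (so it stays binary).  The physical
    extent is preserved to within one voxel; the new grid has
    ``round(n * spacing / target)`` voxels per axis (minimum 1).
    """
    target = tuple(float(t) for t in target_spacing)
    if any(t <= 0 for t in target):
        raise ValueError("target spacing must be positive")
    old_shape = v.intensities.shape
    new_shape = tuple(
        max(1, int(round(n * s / t)))
        for n, s, t in zip(old_shape, v.spacing_mm, target)
    )
    if new_shape == old_shape and target == v.spacing_mm:
        return VolumeWithMask(
            v.intensities.copy(), v.mask.copy(), target, v.origin_mm
        )
    # Voxel-center coordinates of the new grid expressed in old voxel indices.
    coords = np.meshgrid(
        *[
            np.arange(n_new) * t / s
            for n_new, t, s in zip(new_shape, target, v.spacing_mm)
        ],
        indexing="ij",
    )
    coords = np.stack(coords)
    new_int = ndimage.map_coordinates(
        v.intensities, coords, order=1, mode="nearest"
    )
    new_mask = (
        ndimage.map_coordinates(
            v.mask.astype(float), coords, order=1, mode="nearest"
        )
        >= 0.5
    )
    out = VolumeWithMask(new_int, new_mask, target, v.origin_mm)
    if out.n_masked == 0:
        raise EmptyMaskError("mask is empty after resampling")
    return out


def discretize(v: VolumeWithMask, bin_width: float = 25.0) -> GrayVolume:
    """Discretize masked intensities into fixed-width gray-level bins.

    ``level(x) = floor((I(x) - min_masked_I) / bin_width) + 1``.  The minimum
    is taken over masked voxels only; voxels outside the mask get level 0.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    v.require_nonempty()
    lo = v.masked_values().min()
    levels = np.zeros(v.intensities.shape, dtype=np.int64)
    levels[v.mask] = np.floor((v.intensities[v.mask] - lo) / bin_width).astype(
        np.int64
    ) + 1
    return GrayVolume(
        levels=levels,
        n_levels=int(levels[v.mask].max()),
        bin_width=float(bin_width),
        mask=v.mask.copy(),
        spacing_mm=v.spacing_mm,
    )


def discretize_array(
    values: np.ndarray, mask: np.ndarray, bin_width: float,
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> GrayVolume:
    """Discretize an arbitrary response map (e.g. a wavelet band) in-mask."""
    vol = VolumeWithMask(values, mask, spacing_mm)
    return discretize(vol, bin_width)
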