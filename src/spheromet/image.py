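"""Calibrated raster containers used throughout the package.

Every image or mask carries its physical calibration (µm per pixel in x/y,
µm per slice in z for volumes) so that downstream measurements can be
reported in millimetres without threading calibration through every call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CalibratedImage2D",
    "BinaryMask2D",
    "BinaryVolume3D",
    "NoContrastError",
    "CalibrationMismatchError",
]


class NoContrastError(ValueError):
    """Raised when automatic thresholding is undefined (constant image)."""


class CalibrationMismatchError(ValueError):
    """Raised when two inputs carry incompatible physical calibrations."""


@dataclass(frozen=True)
class CalibratedImage2D:
    """A 2D grayscale image with isotropic physical pixel size.

    Parameters
    ----------
    pixels : ndarray
        2D array of intensities, any integer or float dtype. Stored as
        float64.
    pixel_size : float
        Physical size of one pixel in µm (isotropic, > 0).
    """

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"expected a 2D image, got ndim={px.ndim}")
        if px.shape[0] < 16 or px.shape[1] < 16:
            raise ValueError(f"image too small ({px.shape}); need at least 16x16")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite intensities")
        if not (np.isfinite(self.pixel_size) and self.pixel_size > 0):
            raise ValueError(f"pixel_size must be finite and positive, got {self.pixel_size}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BinaryMask2D:
    """A binary cell-vs-background mask carrying the source calibration."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2D mask, got ndim={px.ndim}")
        if not (np.isfinite(self.pixel_size) and self.pixel_size > 0):
            raise ValueError(f"pixel_size must be finite and positive, got {self.pixel_size}")
        object.__setattr__(self, "pixels", px.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def area_px(self) -> int:
        return int(self.pixels.sum())

    def area_mm2(self) -> float:
        """Foreground area in mm² (pixel count × (pixel_size/1000)²)."""
        return self.area_px() * (self.pixel_size / 1000.0) ** 2

    def with_pixels(self, pixels: np.ndarray) -> "BinaryMask2D":
        return BinaryMask2D(pixels, self.pixel_size)


@dataclass(frozen=True)
class BinaryVolume3D:
    """A binary voxel grid (slice, row, col) with anisotropic calibration.

    ``xy_pixel_size`` is the in-plane pixel size in µm; ``z_spacing`` the
    distance between consecutive slices in µm.  All physical geometry
    (distances, ellipsoid fits, shell profiles) uses the anisotropic
    scaling (z·z_spacing, y·xy, x·xy).
    """

    voxels: np.ndarray
    xy_pixel_size: float
    z_spacing: float

    def __post_init__(self):
        vx = np.asarray(self.voxels)
        if vx.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={vx.ndim}")
        for name, v in (("xy_pixel_size", self.xy_pixel_size), ("z_spacing", self.z_spacing)):
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v}")
        object.__setattr__(self, "voxels", vx.astype(bool))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def anisotropy(self) -> float:
        """z/xy spacing ratio."""
        return self.z_spacing / self.xy_pixel_size

    def count(self) -> int:
        return int(self.voxels.sum())

    def voxel_volume_um3(self) -> float:
        return self.xy_pixel_size**2 * self.z_spacing

    def volume_mm3(self) -> float:
        """Foreground volume in mm³ (count × xy² × z / 10⁹)."""
        return self.count() * self.voxel_volume_um3() / 1e9

    def with_voxels(self, voxels: np.ndarray) -> "BinaryVolume3D":
        return BinaryVolume3D(voxels, self.xy_pixel_size, self.z_spacing)
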