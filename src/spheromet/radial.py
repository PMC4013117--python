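"""Radial cell-density profiles around the spheroid centre.

The central descriptor of the method: for a family of concentric digital
circles of growing radius d_i around the spheroid centre, the cell
density at d_i is N_i / P_i — the number of circle pixels that fall on
cells over the total number of circle pixels.  Computed for the whole
mask and for each component of the decomposition, the resulting curves
expose where core, edging and detached cells sit, and integrate back to
the component areas.

The digital circle at radius d_i is the set of pixels whose centre lies
within half a radial step of the ideal circle — the annulus
[d_i − Δd/2, d_i + Δd/2).  Normalising by the pixel count P_i of that
set (rather than 2πd_i) keeps densities in [0, 1] by construction, and
because consecutive circles tile the plane without overlap, integrating
the density curve against the circle sizes recovers component pixel
areas exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decomposition import CoreCircle, SpheroidDecomposition
from .image import CalibrationMismatchError

__all__ = [
    "DensityProfile",
    "ExpansionResult",
    "radial_profile",
    "area_from_profile",
    "max_extent",
    "expansion",
]

_COMPONENTS = ("total", "core", "edging", "detached")


@dataclass(frozen=True)
class DensityProfile:
    """Cell density N_i/P_i on circles of growing radius.

    ``radii_mm`` is strictly increasing with uniform step ``step_mm``;
    each density array has the same length, values in [0, 1].
    """

    radii_mm: np.ndarray
    density_total: np.ndarray
    density_core: np.ndarray
    density_edging: np.ndarray
    density_detached: np.ndarray
    perimeter_px: np.ndarray  # P_i: pixel count of each digital circle
    centre: tuple[float, float]
    pixel_size: float
    step_mm: float

    def density(self, component: str) -> np.ndarray:
        if component not in _COMPONENTS:
            raise KeyError(f"unknown component {component!r}")
        return getattr(self, f"density_{component}")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "distance_mm": self.radii_mm,
                "density_total": self.density_total,
                "density_core": self.density_core,
                "density_edging": self.density_edging,
                "density_detached": self.density_detached,
            }
        )


@dataclass(frozen=True)
class ExpansionResult:
    """Spheroid expansion r_f − r_i (negative = retraction), in mm."""

    r_initial: float
    r_final: float

    @property
    def expansion(self) -> float:
        return self.r_final - self.r_initial


def radial_profile(
    decomposition: SpheroidDecomposition,
    centre: tuple[float, float] | None = None,
    step_mm: float | None = None,
) -> DensityProfile:
    """Density curves for the full mask and each component.

    Parameters
    ----------
    centre : (row, col), optional
        Profile centre in pixels; should be the centre of the *initial*
        spheroid when a t = 0 image exists.  Defaults to the final
        core-circle centre.
    step_mm : float, optional
        Radial step; defaults to one pixel.  Must be at least one pixel.

    Radii run from 0 up to the largest circle fully contained in the
    image.
    """
    pixel_size = decomposition.pixel_size
    if centre is None:
        centre = decomposition.core_circle.centre
    shape = decomposition.core.shape
    if not (0 <= centre[0] <= shape[0] - 1 and 0 <= centre[1] <= shape[1] - 1):
        raise ValueError(f"centre {centre} outside image of shape {shape}")
    px_mm = pixel_size / 1000.0
    if step_mm is None:
        step_mm = px_mm
    step_px = step_mm / px_mm
    if step_px < 1.0 - 1e-9:
        raise ValueError("step below resolution (less than one pixel)")

    rr, cc = np.indices(shape)
    dist = np.hypot(rr - centre[0], cc - centre[1])
    r_max = min(centre[0], shape[0] - 1 - centre[0], centre[1], shape[1] - 1 - centre[1])
    n_radii = int(np.floor(r_max / step_px)) + 1

    radii = np.arange(n_radii) * step_px
    # digital circle i = pixels whose centre lies within step/2 of the
    # ideal circle of radius d_i; consecutive circles tile the plane
    circle_idx = np.round(dist.ravel() / step_px).astype(np.int64)
    in_range = circle_idx < n_radii
    perim = np.bincount(circle_idx[in_range], minlength=n_radii)
    dens = {}
    for name in _COMPONENTS:
        m = decomposition.component(name).pixels.ravel()
        hits = np.bincount(circle_idx[in_range & m], minlength=n_radii)
        dens[name] = np.where(perim > 0, hits / np.maximum(perim, 1), 0.0)

    return DensityProfile(
        radii_mm=radii * px_mm,
        density_total=dens["total"],
        density_core=dens["core"],
        density_edging=dens["edging"],
        density_detached=dens["detached"],
        perimeter_px=perim,
        centre=(float(centre[0]), float(centre[1])),
        pixel_size=pixel_size,
        step_mm=step_px * px_mm,
    )


def area_from_profile(
    profile: DensityProfile,
    component: str = "total",
    d_range: tuple[float, float] | None = None,
) -> float:
    """Area (mm²) under a portion of a density curve.

    The circle-size-weighted integral Σ density_i · P_i · (pixel area)
    over the radii in ``d_range`` (inclusive; full profile when
    omitted) — the discrete counterpart of Σ density · 2π d · Δd.
    Because the digital circles tile the plane, this recovers the
    component's pixel area within the radial band exactly (up to pixels
    beyond the last circle fitting the image).
    """
    dens = profile.density(component)
    d = profile.radii_mm
    if d_range is None:
        sel = np.ones(d.size, dtype=bool)
    else:
        d_lo, d_hi = d_range
        if not d_lo < d_hi:
            raise ValueError(f"empty range ({d_lo}, {d_hi})")
        sel = (d >= d_lo) & (d <= d_hi)
        if not sel.any():
            raise ValueError(f"range ({d_lo}, {d_hi}) contains no profile radii")
    px_area_mm2 = (profile.pixel_size / 1000.0) ** 2
    return float(np.sum(dens[sel] * profile.perimeter_px[sel]) * px_area_mm2)


def max_extent(
    profile: DensityProfile, component: str = "total", min_density: float = 0.0
) -> float:
    """Largest radius (mm) where the component density exceeds ``min_density``.

    With the default ``min_density = 0`` this is the maximum distance
    reached by any cell pixel of the component, as read off the density
    curve; 0 when the component is empty.
    """
    if min_density < 0:
        raise ValueError("min_density must be >= 0")
    dens = profile.density(component)
    above = np.nonzero(dens > min_density)[0]
    if above.size == 0:
        return 0.0
    return float(profile.radii_mm[above[-1]])


def expansion(initial_core: CoreCircle, final_core: CoreCircle) -> ExpansionResult:
    """Spheroid expansion r_f − r_i between the t = 0 and endpoint cores."""
    if not np.isclose(initial_core.pixel_size, final_core.pixel_size, rtol=1e-6):
        raise CalibrationMismatchError(
            f"pixel sizes differ: {initial_core.pixel_size} vs {final_core.pixel_size}"
        )
    return ExpansionResult(r_initial=initial_core.radius_mm, r_final=final_core.radius_mm)
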