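"""Synthetic spheroid phantoms with exact ground truth.

No public microscopy data exist for the sprouting assay, so every
measurement in this package is validated against phantoms: images built
from known geometry — a compact core (disk / ellipsoid) with optional
internal gaps, thin radial sprouts rooted on the core, and detached
cells scattered in the surrounding matrix — plus additive Gaussian
noise and an illumination gradient.  The generator records the exact
component masks, core circle/ellipsoid and object counts, which serve
as ground truth for segmentation, decomposition and all downstream
measurements.

Default geometry mirrors a lymphatic endothelial-cell spheroid imaged
at low magnification: a ~76 µm-radius core (2 µm/px), sprouts reaching
~0.28 mm from the centre and single detached cells of ~4–8 µm radius up
to ~0.32 mm out.  All randomness comes from a single seeded generator;
identical specs give identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .decomposition import CoreCircle
from .image import BinaryMask2D, BinaryVolume3D, CalibratedImage2D
from .volume import CoreEllipsoid

__all__ = [
    "PhantomSpec2D",
    "PhantomSpec3D",
    "PhantomTruth",
    "PhantomTruth3D",
    "OvercrowdedError",
    "make_phantom_2d",
    "make_phantom_pair",
    "make_phantom_3d",
]

_MAX_TRIES = 500


class OvercrowdedError(RuntimeError):
    """Raised when detached objects cannot be placed with the required clearance."""


@dataclass(frozen=True)
class PhantomSpec2D:
    """Geometry and rendering parameters of a 2D phantom.

    Lengths in pixels unless noted.  Detached objects keep a clearance
    of ≥ 2 px from all attached structure (and from each other) so the
    attached/detached ground truth is unambiguous under 8-connectivity.
    """

    image_size: int = 512
    pixel_size: float = 2.0  # µm/px
    core_radius: float = 38.0
    core_hole_radii: tuple[float, ...] = ()
    n_sprouts: int = 8
    sprout_length: float = 100.0
    sprout_width: float = 3.0
    n_detached: int = 12
    detached_radius_range: tuple[float, float] = (2.0, 4.0)
    detached_distance_range: tuple[float, float] = (60.0, 160.0)
    noise_sd: float = 0.0
    illumination_gradient: float = 0.0  # fraction of the fg-bg contrast
    background_level: float = 50.0
    foreground_level: float = 200.0
    brightfield: bool = False  # render cells darker than background
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if not 0 < self.core_radius < self.image_size / 2:
            raise ValueError("core_radius must fit inside the image")
        if self.sprout_width <= 0 or self.sprout_length < 0:
            raise ValueError("sprout geometry must be positive")
        if self.n_sprouts < 0 or self.n_detached < 0:
            raise ValueError("object counts must be >= 0")


@dataclass(frozen=True)
class PhantomTruth:
    """A rendered 2D phantom with its exact ground truth."""

    spec: PhantomSpec2D
    image: CalibratedImage2D
    mask: BinaryMask2D
    core_mask: BinaryMask2D
    edging_mask: BinaryMask2D
    detached_mask: BinaryMask2D
    core_circle: CoreCircle
    n_detached: int
    farthest_cell_distance_px: float

    @property
    def centre(self) -> tuple[float, float]:
        return self.core_circle.centre


def _disk(shape, centre, radius):
    rr, cc = np.indices(shape)
    return np.hypot(rr - centre[0], cc - centre[1]) <= radius


def _render(spec: PhantomSpec2D, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    bg, fg = spec.background_level, spec.foreground_level
    img = np.full(mask.shape, bg, dtype=np.float64)
    img[mask] = fg
    if spec.illumination_gradient:
        ramp = np.linspace(-0.5, 0.5, mask.shape[1])
        img = img + spec.illumination_gradient * (fg - bg) * ramp[None, :]
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=mask.shape)
    if spec.brightfield:
        img = (fg + bg) - img
    return img


def make_phantom_2d(spec: PhantomSpec2D) -> PhantomTruth:
    """Render a 2D phantom and its exact decomposition ground truth.

    The ground-truth decomposition follows the method's own definition:
    the core is the mask inside the programmed core circle, sprout parts
    beyond the circle are edging, and the scattered objects detached.

    Raises
    ------
    OvercrowdedError
        If a detached object cannot be placed with 2 px clearance after
        bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    shape = (n, n)
    # integer-pixel centre: keeps the rasterised core's inscribed circle
    # aligned with the programmed one
    centre = (float(n // 2), float(n // 2))
    rr, cc = np.indices(shape)
    dist = np.hypot(rr - centre[0], cc - centre[1])

    core = dist <= spec.core_radius

    holes = np.zeros(shape, dtype=bool)
    for hr in spec.core_hole_radii:
        max_off = spec.core_radius - hr - 3.0
        if max_off <= 0:
            raise ValueError(f"hole of radius {hr} does not fit inside the core")
        for _ in range(_MAX_TRIES):
            ang = rng.uniform(0, 2 * np.pi)
            off = rng.uniform(0, max_off)
            hc = (centre[0] + off * np.sin(ang), centre[1] + off * np.cos(ang))
            h = _disk(shape, hc, hr)
            if not (h & holes).any():
                holes |= h
                break
        else:
            raise OvercrowdedError("spec overcrowded: cannot place core hole")

    sprouts = np.zeros(shape, dtype=bool)
    if spec.n_sprouts > 0:
        base = rng.uniform(0, 2 * np.pi)
        jitter = rng.uniform(-0.25, 0.25, size=spec.n_sprouts)
        angles = base + np.arange(spec.n_sprouts) * 2 * np.pi / spec.n_sprouts + jitter
        py = rr - centre[0]
        px = cc - centre[1]
        for ang in angles:
            uy, ux = np.sin(ang), np.cos(ang)
            t = py * uy + px * ux  # radial coordinate along the sprout
            s = -py * ux + px * uy  # transverse coordinate
            sprouts |= (
                (t >= spec.core_radius - 2.0)
                & (t <= spec.core_radius + spec.sprout_length)
                & (np.abs(s) <= spec.sprout_width / 2.0)
            )
    sprouts &= dist <= (n - 1) / 2.0  # keep sprout tips inside the frame

    attached = (core & ~holes) | sprouts

    detached = np.zeros(shape, dtype=bool)
    occupied = attached.copy()
    lo_d, hi_d = spec.detached_distance_range
    lo_r, hi_r = spec.detached_radius_range
    for _ in range(spec.n_detached):
        clearance = ndimage.distance_transform_edt(~occupied)
        for _ in range(_MAX_TRIES):
            ang = rng.uniform(0, 2 * np.pi)
            d = rng.uniform(lo_d, hi_d)
            rho = rng.uniform(lo_r, hi_r)
            oc = (centre[0] + d * np.sin(ang), centre[1] + d * np.cos(ang))
            if not (
                rho + 1 <= oc[0] <= n - 2 - rho and rho + 1 <= oc[1] <= n - 2 - rho
            ):
                continue
            obj = _disk(shape, oc, rho)
            if clearance[obj].min() >= 2.0:
                detached |= obj
                occupied |= obj
                break
        else:
            raise OvercrowdedError("spec overcrowded: cannot place detached object")

    mask = attached | detached
    core_truth = attached & (dist <= spec.core_radius)
    edging_truth = attached & ~core_truth
    ps = spec.pixel_size

    image = CalibratedImage2D(_render(spec, mask, rng), ps)
    farthest = float(dist[mask].max()) if mask.any() else 0.0
    return PhantomTruth(
        spec=spec,
        image=image,
        mask=BinaryMask2D(mask, ps),
        core_mask=BinaryMask2D(core_truth, ps),
        edging_mask=BinaryMask2D(edging_truth, ps),
        detached_mask=BinaryMask2D(detached, ps),
        core_circle=CoreCircle(centre, spec.core_radius, ps),
        n_detached=spec.n_detached,
        farthest_cell_distance_px=farthest,
    )


def make_phantom_pair(
    spec_t0: PhantomSpec2D,
    expansion_px: float,
    spec_t1: PhantomSpec2D | None = None,
) -> tuple[PhantomTruth, PhantomTruth]:
    """A co-centred (t = 0, endpoint) phantom pair with programmed expansion.

    ``spec_t1`` defaults to ``spec_t0`` with the core radius enlarged by
    ``expansion_px`` (negative = retraction) and a distinct seed; when
    given, its core radius must equal ``spec_t0.core_radius +
    expansion_px``.
    """
    if spec_t1 is None:
        spec_t1 = replace(
            spec_t0, core_radius=spec_t0.core_radius + expansion_px, seed=spec_t0.seed + 1
        )
    elif not np.isclose(spec_t1.core_radius, spec_t0.core_radius + expansion_px):
        raise ValueError(
            "spec_t1.core_radius must equal spec_t0.core_radius + expansion_px"
        )
    return make_phantom_2d(spec_t0), make_phantom_2d(spec_t1)


@dataclass(frozen=True)
class PhantomSpec3D:
    """Geometry of a 3D phantom rendered into an anisotropic voxel grid.

    ``core_semi_axes`` are in voxels along (z, y, x); physical semi-axes
    follow from the calibrations.  The default stack is cropped in z to
    the spheroid — every slice intersects the core, as when the scan
    covers exactly the z extent of the object — so per-slice automatic
    thresholding always sees real signal.  Rod lengths/radii and detached-ball
    radii are physical (µm); detached distances are in units of the core
    ellipsoidal coordinate u (u = 1 on the core surface).
    """

    shape: tuple[int, int, int] = (24, 256, 256)
    xy_pixel_size: float = 4.0  # µm
    z_spacing: float = 6.0  # µm
    core_semi_axes: tuple[float, float, float] = (12.5, 22.0, 18.0)  # voxels (z, y, x)
    n_rods: int = 8
    rod_length: float = 100.0  # µm
    rod_radius: float = 6.0  # µm
    n_detached: int = 6
    detached_radius: tuple[float, float] = (8.0, 14.0)  # µm
    detached_distance_u: tuple[float, float] = (1.5, 2.4)
    noise_sd: float = 0.0
    background_level: float = 20.0
    foreground_level: float = 200.0
    seed: int = 0

    def __post_init__(self):
        if self.shape[0] < 8 or self.shape[1] < 16 or self.shape[2] < 16:
            raise ValueError("volume too small")
        if any(a <= 0 for a in self.core_semi_axes):
            raise ValueError("core semi-axes must be positive")


@dataclass(frozen=True)
class PhantomTruth3D:
    """A rendered 3D phantom (per-slice images) with exact ground truth."""

    spec: PhantomSpec3D
    slices: tuple[CalibratedImage2D, ...]
    volume: BinaryVolume3D
    core_volume: BinaryVolume3D
    edging_volume: BinaryVolume3D
    detached_volume: BinaryVolume3D
    core_ellipsoid: CoreEllipsoid
    n_detached: int
    rod_z_extents: tuple[int, ...]
    detached_z_extents: tuple[int, ...]
    farthest_cell_distance_um: float


def make_phantom_3d(spec: PhantomSpec3D) -> PhantomTruth3D:
    """Render an ellipsoid-core 3D phantom with radial rods and detached balls.

    Ground-truth decomposition: voxels with ellipsoidal coordinate u ≤ 1
    are core, attached rod parts beyond are edging, scattered balls
    detached.  Truth volumes are exact voxel counts.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    spacing = np.array([spec.z_spacing, spec.xy_pixel_size, spec.xy_pixel_size])
    centre_vox = np.array([(nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0])
    axes_phys = np.array(spec.core_semi_axes) * spacing

    zz, yy, xx = np.indices(spec.shape)
    phys = np.stack(
        [
            (zz - centre_vox[0]) * spacing[0],
            (yy - centre_vox[1]) * spacing[1],
            (xx - centre_vox[2]) * spacing[2],
        ],
        axis=-1,
    )
    u = np.sqrt(((phys / axes_phys) ** 2).sum(axis=-1))
    core = u <= 1.0

    def z_extent(vox: np.ndarray) -> int:
        zs = np.nonzero(vox.any(axis=(1, 2)))[0]
        return int(zs.max() - zs.min() + 1) if zs.size else 0

    rods = np.zeros(spec.shape, dtype=bool)
    rod_exts = []
    for _ in range(spec.n_rods):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        t_exit = 1.0 / np.sqrt(((v / axes_phys) ** 2).sum())
        t = phys @ v
        perp = np.sqrt(np.maximum((phys**2).sum(axis=-1) - t**2, 0.0))
        rod = (
            (t >= t_exit - 2 * spec.xy_pixel_size)
            & (t <= t_exit + spec.rod_length)
            & (perp <= spec.rod_radius)
        )
        rods |= rod
        rod_exts.append(z_extent(rod))
    attached = core | rods

    detached = np.zeros(spec.shape, dtype=bool)
    det_exts = []
    occupied = attached.copy()
    for _ in range(spec.n_detached):
        clearance = ndimage.distance_transform_edt(~occupied)
        for _ in range(_MAX_TRIES):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            uu = rng.uniform(*spec.detached_distance_u)
            rho = rng.uniform(*spec.detached_radius)
            t_exit = 1.0 / np.sqrt(((v / axes_phys) ** 2).sum())
            c_phys = uu * t_exit * v
            c_vox = centre_vox + c_phys / spacing
            r_vox = rho / spacing  # per-axis radius in voxels
            if not np.all((c_vox - r_vox >= 1) & (c_vox + r_vox <= np.array(spec.shape) - 2)):
                continue
            d_phys = np.sqrt(((phys - c_phys) ** 2).sum(axis=-1))
            ball = d_phys <= rho
            if not ball.any():
                continue
            if clearance[ball].min() >= 2.0:
                detached |= ball
                occupied |= ball
                det_exts.append(z_extent(ball))
                break
        else:
            raise OvercrowdedError("spec overcrowded: cannot place detached ball")

    mask = attached | detached
    core_truth = mask & (u <= 1.0)
    edging_truth = attached & ~core_truth

    vol = BinaryVolume3D(mask, spec.xy_pixel_size, spec.z_spacing)
    slices = []
    spec2d = PhantomSpec2D(
        image_size=max(ny, 16),
        pixel_size=spec.xy_pixel_size,
        background_level=spec.background_level,
        foreground_level=spec.foreground_level,
        noise_sd=spec.noise_sd,
    )
    for k in range(nz):
        img = _render(spec2d, mask[k], rng)
        slices.append(CalibratedImage2D(img, spec.xy_pixel_size))

    farthest = float(np.sqrt((phys[mask] ** 2).sum(axis=-1)).max()) if mask.any() else 0.0
    return PhantomTruth3D(
        spec=spec,
        slices=tuple(slices),
        volume=vol,
        core_volume=vol.with_voxels(core_truth),
        edging_volume=vol.with_voxels(edging_truth),
        detached_volume=vol.with_voxels(detached),
        core_ellipsoid=CoreEllipsoid(
            tuple(centre_vox), tuple(axes_phys), np.eye(3)
        ),
        n_detached=spec.n_detached,
        rod_z_extents=tuple(rod_exts),
        detached_z_extents=tuple(det_exts),
        farthest_cell_distance_um=farthest,
    )
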