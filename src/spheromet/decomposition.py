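"""Decomposition of a binary spheroid mask into core, edging and detached cells.

The frontier between the spheroid body and the migrating cells is the
largest circle inscribed in the filled spheroid component (internal gaps
— holes not connected to the exterior — count as body).  Mask pixels
inside that circle form the *core*; components of the remainder that
touch the core (8-adjacency) are *edging* (migrating but still attached)
cells; everything else is *detached*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label

from .image import BinaryMask2D

__all__ = [
    "CoreCircle",
    "SpheroidDecomposition",
    "fill_internal_holes",
    "largest_inscribed_circle",
    "decompose",
    "count_detached_objects",
]


@dataclass(frozen=True)
class CoreCircle:
    """The largest inscribed circle delimiting the spheroid core.

    ``centre`` is (row, col) in pixels; ``radius`` in pixels;
    ``pixel_size`` in µm.
    """

    centre: tuple[float, float]
    radius: float
    pixel_size: float

    def __post_init__(self):
        if not self.radius > 0:
            raise ValueError(f"radius must be positive, got {self.radius}")

    @property
    def radius_mm(self) -> float:
        return self.radius * self.pixel_size / 1000.0


@dataclass(frozen=True)
class SpheroidDecomposition:
    """Pairwise-disjoint core / edging / detached masks whose union is the input."""

    core: BinaryMask2D
    edging: BinaryMask2D
    detached: BinaryMask2D
    core_circle: CoreCircle

    @property
    def pixel_size(self) -> float:
        return self.core.pixel_size

    def total_mask(self) -> BinaryMask2D:
        return self.core.with_pixels(
            self.core.pixels | self.edging.pixels | self.detached.pixels
        )

    def component(self, name: str) -> BinaryMask2D:
        if name == "total":
            return self.total_mask()
        try:
            return getattr(self, name)
        except AttributeError:
            raise KeyError(f"unknown component {name!r}") from None


def fill_internal_holes(mask: BinaryMask2D) -> BinaryMask2D:
    """Fill background regions not 4-connected to the image border."""
    return mask.with_pixels(ndimage.binary_fill_holes(mask.pixels))


def _largest_component(mask_px: np.ndarray) -> np.ndarray:
    lbl, n = label(mask_px, connectivity=2, return_num=True)
    if n <= 1:
        return mask_px.copy()
    sizes = np.bincount(lbl.ravel())
    sizes[0] = 0
    return lbl == int(np.argmax(sizes))

def largest_inscribed_circle(mask: BinaryMask2D) -> CoreCircle:
    """Largest circle inscribed in the filled spheroid body.

    Computed as the global maximum of the Euclidean distance transform
    of the hole-filled largest 8-connected component; thin appendages
    (sprouts) cannot host the maximal circle, so the result is
    insensitive to them.  When several pixels attain the maximal
    distance, the one closest to the centroid of the filled body is
    chosen (deterministic, and keeps the circle at the spheroid's
    body).

    Raises
    ------
    ValueError
        If the mask has no foreground.
    """
    if not mask.pixels.any():
        raise ValueError("no foreground")
    body = ndimage.binary_fill_holes(_largest_component(mask.pixels))
    if body.all():
        # no in-image background: the circle is limited by the frame
        edt = ndimage.distance_transform_edt(np.pad(body, 1))[1:-1, 1:-1]
    else:
        edt = ndimage.distance_transform_edt(body)
    radius = float(edt.max())
    cand = np.argwhere(edt == edt.max())
    centroid = np.argwhere(body).mean(axis=0)
    best = cand[np.argmin(((cand - centroid) ** 2).sum(axis=1))]
    return CoreCircle((float(best[0]), float(best[1])), radius, mask.pixel_size)


def decompose(mask: BinaryMask2D, core_circle: CoreCircle) -> SpheroidDecomposition:
    """Split ``mask`` into core / edging / detached using ``core_circle``.

    Core = mask pixels whose centre lies inside the circle.  Among the
    8-connected components of the remainder, those sharing at least one
    8-adjacency with a core pixel are edging; the rest are detached.
    The three masks are pairwise disjoint and their union is ``mask``.
    """
    rr, cc = np.indices(mask.shape)
    dist = np.hypot(rr - core_circle.centre[0], cc - core_circle.centre[1])
    core = mask.pixels & (dist <= core_circle.radius + 1e-9)
    if not core.any():
        raise ValueError("core circle does not intersect mask")
    rest = mask.pixels & ~core
    edging = np.zeros(mask.shape, dtype=bool)
    detached = np.zeros(mask.shape, dtype=bool)
    if rest.any():
        lbl, n = label(rest, connectivity=2, return_num=True)
        halo = ndimage.binary_dilation(core, structure=np.ones((3, 3), bool))
        touching = np.unique(lbl[halo & rest])
        touching = touching[touching > 0]
        is_edge = np.zeros(n + 1, dtype=bool)
        is_edge[touching] = True
        edging = is_edge[lbl]
        detached = rest & ~edging
    return SpheroidDecomposition(
        core=mask.with_pixels(core),
        edging=mask.with_pixels(edging),
        detached=mask.with_pixels(detached),
        core_circle=core_circle,
    )


def count_detached_objects(decomposition: SpheroidDecomposition) -> int:
    """Number of 8-connected components of the detached mask."""
    _, n = label(decomposition.detached.pixels, connectivity=2, return_num=True)
    return int(n)
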