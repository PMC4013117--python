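"""2D segmentation of spheroid images into binary cell masks.

Two situations arise in the sprouting assay.  The freshly embedded
spheroid (t = 0) is a single well-contrasted blob, and a global threshold
(:func:`binarize_simple`) is enough.  After culture the image mixes a
bright compact core with thin, faint sprouts and scattered single cells;
there :func:`binarize_invasion` enhances elongated structures with the
multiscale Frangi vesselness filter before thresholding, merges the
result with the global-threshold mask of the bright core, and removes
sub-cellular specks.

Brightfield images show cells *darker* than the background; the
``invert`` flag in :class:`SegmentationConfig` negates intensities before
any thresholding or vesselness computation so that "foreground" always
means bright.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import filters
from skimage.measure import label

from .image import BinaryMask2D, CalibratedImage2D, NoContrastError

__all__ = [
    "SegmentationConfig",
    "otsu_threshold",
    "binarize_simple",
    "frangi_enhance",
    "binarize_invasion",
    "remove_small_objects",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Parameters of the 2D segmentation pipeline.

    Attributes
    ----------
    frangi_scales : tuple of float
        Gaussian scales (px) of the vesselness filter; the per-pixel
        response is the maximum over scales.
    frangi_threshold_quantile : float
        Quantile (of the nonzero vesselness responses) at which the
        vesselness image is thresholded.
    min_object_area : float
        Connected components (8-connectivity) smaller than this physical
        area (µm²) are removed from the final mask.  The default, 20 µm²,
        is below the footprint of a single ~5 µm cell.
    threshold_method : {"otsu", "fixed"}
        Global threshold selection for the simple binarisation.
    fixed_threshold : float
        Threshold used when ``threshold_method == "fixed"`` (applied to
        the possibly inverted intensities).
    invert : bool
        Negate intensities first (brightfield: cells darker than
        background).
    frangi_beta : float
        Blob-vs-line sensitivity of the vesselness filter.
    """

    frangi_scales: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)
    frangi_threshold_quantile: float = 0.90
    min_object_area: float = 20.0
    threshold_method: str = "otsu"
    fixed_threshold: float = 0.0
    invert: bool = False
    frangi_beta: float = 0.5

    def __post_init__(self):
        if len(self.frangi_scales) == 0:
            raise ValueError("frangi_scales must be non-empty")
        if any(s <= 0 for s in self.frangi_scales):
            raise ValueError("frangi_scales must be strictly positive")
        if not 0.0 < self.frangi_threshold_quantile < 1.0:
            raise ValueError("frangi_threshold_quantile must lie in (0, 1)")
        if self.min_object_area < 0:
            raise ValueError("min_object_area must be >= 0")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")


def otsu_threshold(values: np.ndarray) -> float:
    """Otsu's between-class-variance-maximising global threshold.

    For integer-valued input every occurring integer level is a candidate
    threshold, so the result is exactly the exhaustive-search maximiser
    (binarisation rule: ``value > threshold`` is foreground).  Float input
    is binned into 256 levels.
    """
    vals = np.asarray(values).ravel()
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmin == vmax:
        raise NoContrastError("no contrast, threshold undefined (constant image)")
    if np.issubdtype(np.asarray(values).dtype, np.integer) or np.all(vals == np.round(vals)):
        levels = np.arange(int(vmin), int(vmax) + 1, dtype=np.float64)
        counts = np.bincount((vals - int(vmin)).astype(np.int64), minlength=levels.size)
        return float(filters.threshold_otsu(hist=(counts, levels)))
    return float(filters.threshold_otsu(vals, nbins=256))


def _working_intensities(image: CalibratedImage2D, config: SegmentationConfig) -> np.ndarray:
    return -image.pixels if config.invert else image.pixels


def binarize_simple(image: CalibratedImage2D, config: SegmentationConfig) -> BinaryMask2D:
    """Global-threshold binarisation for well-contrasted images.

    Intensities are negated first when ``config.invert`` is set; pixels
    strictly above the (Otsu-selected or fixed) threshold become
    foreground.

    Raises
    ------
    NoContrastError
        If ``threshold_method == "otsu"`` and the image is constant.
    """
    work = _working_intensities(image, config)
    if config.threshold_method == "otsu":
        thresh = otsu_threshold(work)
    else:
        thresh = config.fixed_threshold
    return BinaryMask2D(work > thresh, image.pixel_size)


def frangi_enhance(image: CalibratedImage2D, config: SegmentationConfig) -> CalibratedImage2D:
    """Multiscale vesselness response highlighting elongated structures.

    Returns a non-negative response image of the same shape; per pixel
    the maximum response over ``config.frangi_scales`` is taken.  Bright
    ridges respond (after the optional inversion), so brightfield sprouts
    are enhanced when ``invert`` is set.
    """
    work = _working_intensities(image, config)
    resp = filters.frangi(
        work,
        sigmas=config.frangi_scales,
        beta=config.frangi_beta,
        black_ridges=False,
    )
    resp = np.clip(resp, 0.0, None)
    return CalibratedImage2D(resp, image.pixel_size)


def binarize_invasion(image: CalibratedImage2D, config: SegmentationConfig) -> BinaryMask2D:
    """Segment an endpoint (t > 0) spheroid image.

    The vesselness response is thresholded at
    ``frangi_threshold_quantile`` of its nonzero values (vesselness has
    no absolute scale), OR-combined with the simple global-threshold mask
    that captures the bright compact core, and finally cleaned with
    :func:`remove_small_objects`.

    In a noisy image the response is not exactly zero anywhere, so
    "nonzero" is operationalised as the upper class of Otsu's split of
    the positive response values: the noise floor forms the lower class
    and the quantile is taken over the supported (structure) responses
    only.  This reduces to the literal nonzero support on noise-free
    images, where the background response vanishes.

    A blank (structure-free, constant) image yields an empty mask.
    """
    resp = frangi_enhance(image, config).pixels
    rmax = float(resp.max())
    vessel = np.zeros(image.shape, dtype=bool)
    if rmax > 0:
        pos = resp[resp > 0]
        try:
            support = resp > otsu_threshold(pos)
        except NoContrastError:
            support = resp > 0
        cut = float(np.quantile(resp[support], config.frangi_threshold_quantile))
        vessel = resp > cut
    try:
        core = binarize_simple(image, config).pixels
    except NoContrastError:
        core = np.zeros(image.shape, dtype=bool)
    mask = BinaryMask2D(vessel | core, image.pixel_size)
    return remove_small_objects(mask, config.min_object_area)


def remove_small_objects(mask: BinaryMask2D, min_area: float) -> BinaryMask2D:
    """Delete 8-connected components with physical area < ``min_area`` µm²."""
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    if min_area == 0 or not mask.pixels.any():
        return mask
    min_px = min_area / mask.pixel_size**2
    lbl, n = label(mask.pixels, connectivity=2, return_num=True)
    if n == 0:
        return mask
    sizes = np.bincount(lbl.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return mask.with_pixels(keep[lbl])
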