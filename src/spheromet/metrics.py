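"""Global invasion parameters and per-spheroid measurement reports.

Implements the classical global descriptors (convex envelope area,
invasion distances d1/d2, total cell area) alongside the per-component
areas from the decomposition, aggregated into a single
:class:`MeasurementReport` per spheroid, plus group statistics
(mean ± SEM, percent inhibition/stimulation) across spheroids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .decomposition import CoreCircle, SpheroidDecomposition, count_detached_objects
from .image import BinaryMask2D, CalibrationMismatchError
from .radial import DensityProfile, expansion

__all__ = [
    "MeasurementReport",
    "PercentChange",
    "envelope_area",
    "invasion_distances",
    "measure",
    "percent_change",
    "group_summary",
]


@dataclass
class MeasurementReport:
    """All scalar measurements for one spheroid.

    Areas in mm², distances in mm, volumes (3D pipeline only) in mm³.
    ``total_cell_area = core_area + edging_area + detached_area`` holds
    exactly in pixel counts; ``envelope_area >= total_cell_area`` always.
    ``expansion_mm`` is present only when a t = 0 image was supplied.
    """

    envelope_area: float
    total_cell_area: float
    d1: float
    d2: float
    core_area: float
    edging_area: float
    detached_area: float
    n_detached: int
    core_radius_mm: float
    expansion_mm: float | None = None
    total_cell_volume: float | None = None
    core_volume: float | None = None
    edging_volume: float | None = None
    detached_volume: float | None = None

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def envelope_area(mask: BinaryMask2D) -> float:
    """Area (mm²) of the minimal convex polygon containing all cell pixels.

    Computed on pixel centres (no half-pixel dilation correction, so the
    value is biased low by at most ~perimeter/2 px²).  Degenerate masks
    (all pixels collinear) have zero hull area.
    """
    pts = np.argwhere(mask.pixels)
    if pts.size == 0:
        raise ValueError("empty mask")
    scale = (mask.pixel_size / 1000.0) ** 2
    if len(pts) < 3:
        return 0.0
    from scipy.spatial import ConvexHull, QhullError

    try:
        hull = ConvexHull(pts.astype(float))
    except QhullError:
        return 0.0  # collinear points
    return float(hull.volume) * scale  # ConvexHull.volume is the area in 2D


def invasion_distances(
    decomposition: SpheroidDecomposition,
    profile_centre: tuple[float, float] | None = None,
    r_reference_mm: float | None = None,
) -> tuple[float, float]:
    """The classical invasion distances (d1, d2) in mm.

    d1 is the distance from the profile centre to the farthest cell
    pixel; d2 = d1 − r, where r is the final core radius by default (or
    the supplied reference radius, e.g. the initial one), clipped at 0.
    """
    if profile_centre is None:
        profile_centre = decomposition.core_circle.centre
    total = decomposition.total_mask().pixels
    pts = np.argwhere(total)
    if pts.size == 0:
        raise ValueError("empty mask")
    d = np.hypot(pts[:, 0] - profile_centre[0], pts[:, 1] - profile_centre[1])
    d1 = float(d.max()) * decomposition.pixel_size / 1000.0
    if r_reference_mm is None:
        r_reference_mm = decomposition.core_circle.radius_mm
    d2 = max(d1 - r_reference_mm, 0.0)
    return d1, d2


def measure(
    decomposition: SpheroidDecomposition,
    profile: DensityProfile | None = None,
    initial: CoreCircle | None = None,
    d2_reference: str = "final_core",
) -> MeasurementReport:
    """Assemble the full per-spheroid measurement report.

    Parameters
    ----------
    initial : CoreCircle, optional
        Core circle of the t = 0 image; enables the expansion
        measurement, and (with ``d2_reference="initial_core"``) an
        expansion-aware d2.
    d2_reference : {"final_core", "initial_core"}
        Which core radius is subtracted from d1 to obtain d2.  The
        conventional choice, ``final_core``, ignores spheroid expansion
        between embedding and endpoint.
    """
    if profile is not None and not math.isclose(
        profile.pixel_size, decomposition.pixel_size, rel_tol=1e-6
    ):
        raise CalibrationMismatchError("profile and decomposition pixel sizes differ")
    if d2_reference not in ("final_core", "initial_core"):
        raise ValueError(f"unknown d2_reference {d2_reference!r}")
    if d2_reference == "initial_core" and initial is None:
        raise ValueError("d2_reference='initial_core' requires the initial core circle")

    centre = profile.centre if profile is not None else None
    r_ref = None
    if d2_reference == "initial_core":
        r_ref = initial.radius_mm
    d1, d2 = invasion_distances(decomposition, centre, r_ref)

    exp_mm = None
    if initial is not None:
        exp_mm = expansion(initial, decomposition.core_circle).expansion

    total = decomposition.total_mask()
    return MeasurementReport(
        envelope_area=envelope_area(total),
        total_cell_area=total.area_mm2(),
        d1=d1,
        d2=d2,
        core_area=decomposition.core.area_mm2(),
        edging_area=decomposition.edging.area_mm2(),
        detached_area=decomposition.detached.area_mm2(),
        n_detached=count_detached_objects(decomposition),
        core_radius_mm=decomposition.core_circle.radius_mm,
        expansion_mm=exp_mm,
    )


@dataclass(frozen=True)
class PercentChange:
    """Inhibition/stimulation percentage between two experimental groups.

    ``kind`` is "inhibition" when the treated mean is below the control
    mean and "stimulation" otherwise; ``percent`` is positive in both
    cases, expressed relative to the larger of the two group means (the
    convention under which published spheroid-assay tables report their
    inhibition and stimulation columns).
    """

    kind: str
    percent: float
    mean_control: float
    sem_control: float | None
    mean_treated: float
    sem_treated: float | None


def _mean_sem(values: np.ndarray) -> tuple[float, float | None]:
    m = float(np.mean(values))
    if values.size < 2:
        return m, None
    return m, float(np.std(values, ddof=1) / np.sqrt(values.size))


def percent_change(
    treated,
    control,
    field_name: str | None = None,
) -> PercentChange:
    """Percent inhibition/stimulation of ``field_name`` between groups.

    ``treated`` and ``control`` are lists of :class:`MeasurementReport`
    (with ``field_name``) or plain numeric sequences.  Raises on a zero
    denominator.
    """
    def _values(group):
        if field_name is not None and len(group) and hasattr(group[0], field_name):
            vals = [getattr(r, field_name) for r in group]
        else:
            vals = list(group)
        if len(vals) == 0:
            raise ValueError("empty group")
        if any(v is None for v in vals):
            raise ValueError(f"missing values for field {field_name!r}")
        return np.asarray(vals, dtype=float)

    t = _values(treated)
    c = _values(control)
    mc, sc = _mean_sem(c)
    mt, st = _mean_sem(t)
    denom = max(mc, mt)
    if denom == 0:
        raise ValueError("zero group means: percent change undefined")
    if mt <= mc:
        kind, pct = "inhibition", 100.0 * (mc - mt) / mc
    else:
        kind, pct = "stimulation", 100.0 * (mt - mc) / mt
    return PercentChange(kind, pct, mc, sc, mt, st)


def group_summary(reports_by_group: dict[str, list[MeasurementReport]]):
    """Mean ± SEM per report field for each group, as a tidy DataFrame.

    SEM is reported as missing for single-spheroid groups.
    """
    import pandas as pd

    rows = []
    for group, reports in reports_by_group.items():
        if len(reports) == 0:
            raise ValueError(f"group {group!r} is empty")
        for f in fields(MeasurementReport):
            vals = [getattr(r, f.name) for r in reports]
            if any(v is None for v in vals):
                continue
            arr = np.asarray(vals, dtype=float)
            m, s = _mean_sem(arr)
            rows.append(
                {"group": group, "measurement": f.name, "mean": m, "sem": s, "n": len(arr)}
            )
    return pd.DataFrame(rows)
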