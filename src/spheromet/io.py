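"""File I/O, run configuration and end-to-end pipelines.

Readers accept single-page TIFF/PNG (2D) and multi-page TIFF (3D
stacks), 8/12/16-bit grayscale; calibration comes from the caller or a
config file, never from image metadata.  Writers emit a JSON
measurement report per spheroid, CSV density/shell profiles, and a
label TIFF of the decomposition (0 = background, 1 = core, 2 = edging,
3 = detached).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .decomposition import (
    SpheroidDecomposition,
    decompose,
    largest_inscribed_circle,
)
from .image import BinaryMask2D, CalibratedImage2D
from .metrics import MeasurementReport, group_summary, measure, percent_change
from .phantom import PhantomSpec2D
from .radial import DensityProfile, radial_profile
from .segmentation import SegmentationConfig, binarize_invasion, binarize_simple
from .volume import (
    decompose_3d,
    fit_core_ellipsoid,
    measure_3d,
    preprocess_stack,
    remove_spurious_3d,
    shell_profile_3d,
)

logger = logging.getLogger("spheromet")

__all__ = [
    "RunConfig",
    "read_image_2d",
    "read_stack",
    "write_label_image",
    "analyze_image_2d",
    "run_2d",
    "run_3d",
    "run_batch",
]


@dataclass
class RunConfig:
    """User-facing configuration of an analysis run.

    Serialisable to/from a plain JSON file; keys mirror the field names,
    with the segmentation sub-config nested under ``"segmentation"``.
    """

    mode: str = "2d"
    pixel_size_um: float = 1.0
    z_spacing_um: float | None = None
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    radial_step_mm: float | None = None  # None: one pixel
    shell_step: float = 0.05
    d2_reference: str = "final_core"
    min_slices_3d: int = 3
    maxpool: bool = True
    output_dir: str = "."
    plot: bool = False

    def __post_init__(self):
        if self.mode not in ("2d", "3d"):
            raise ValueError(f"mode must be '2d' or '3d', got {self.mode!r}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.mode == "3d" and (self.z_spacing_um is None or self.z_spacing_um <= 0):
            raise ValueError("3d mode requires a positive z_spacing_um")

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d["segmentation"]["frangi_scales"] = list(self.segmentation.frangi_scales)
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        seg = d.pop("segmentation", {})
        if "frangi_scales" in seg:
            seg["frangi_scales"] = tuple(seg["frangi_scales"])
        return cls(segmentation=SegmentationConfig(**seg), **d)


def read_image_2d(path, pixel_size_um: float) -> CalibratedImage2D:
    """Read a single-page TIFF or PNG grayscale image."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # collapse RGB(A) to gray
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single 2D image, got shape {arr.shape}")
    return CalibratedImage2D(arr, pixel_size_um)


def read_stack(path, pixel_size_um: float) -> list[CalibratedImage2D]:
    """Read a multi-page TIFF as a list of slices (one channel)."""
    import tifffile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = np.asarray(tifffile.imread(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 4 and arr.shape[-1] in (3, 4):
        # RGB stack: keep the first (red) channel, where cells are stained
        arr = arr[..., 0]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a z-stack, got shape {arr.shape}")
    return [CalibratedImage2D(sl, pixel_size_um) for sl in arr]


def write_label_image(path, decomposition: SpheroidDecomposition) -> None:
    """Write the decomposition as a uint8 label TIFF (1=core 2=edging 3=detached)."""
    import tifffile

    lbl = np.zeros(decomposition.core.shape, dtype=np.uint8)
    lbl[decomposition.core.pixels] = 1
    lbl[decomposition.edging.pixels] = 2
    lbl[decomposition.detached.pixels] = 3
    tifffile.imwrite(path, lbl)


def analyze_image_2d(
    image: CalibratedImage2D,
    config: RunConfig,
    t0_image: CalibratedImage2D | None = None,
) -> tuple[SpheroidDecomposition, DensityProfile, MeasurementReport]:
    """Full 2D analysis of one spheroid image (optionally with its t = 0 image).

    Segmentation → largest-inscribed-circle decomposition → radial
    density profile (centred on the initial spheroid when available,
    else on the final core with a logged warning) → measurement report.
    """
    mask = binarize_invasion(image, config.segmentation)
    if not mask.pixels.any():
        raise ValueError("segmentation produced an empty mask")
    circle = largest_inscribed_circle(mask)
    decomposition = decompose(mask, circle)

    initial = None
    if t0_image is not None:
        t0_mask = binarize_simple(t0_image, config.segmentation)
        initial = largest_inscribed_circle(t0_mask)
        centre = initial.centre
    else:
        logger.warning(
            "no t=0 image: centring the profile on the final core; "
            "expansion will not be measured"
        )
        centre = circle.centre
    profile = radial_profile(decomposition, centre=centre, step_mm=config.radial_step_mm)
    report = measure(
        decomposition, profile, initial=initial, d2_reference=config.d2_reference
    )
    return decomposition, profile, report


def _report_to_json(report: MeasurementReport, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))


def run_2d(
    t_image_path,
    config: RunConfig,
    t0_image_path=None,
    stem: str | None = None,
) -> MeasurementReport:
    """Analyse one 2D spheroid image and write report, profile and masks.

    Outputs in ``config.output_dir``: ``<stem>_report.json``,
    ``<stem>_density.csv``, ``<stem>_labels.tif`` and (with
    ``config.plot``) ``<stem>_density.png``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = stem or Path(t_image_path).stem
    image = read_image_2d(t_image_path, config.pixel_size_um)
    t0 = read_image_2d(t0_image_path, config.pixel_size_um) if t0_image_path else None
    decomposition, profile, report = analyze_image_2d(image, config, t0)
    _report_to_json(report, out / f"{stem}_report.json")
    profile.to_dataframe().to_csv(out / f"{stem}_density.csv", index=False)
    write_label_image(out / f"{stem}_labels.tif", decomposition)
    if config.plot:
        from .plotting import plot_density_profile

        plot_density_profile(profile, out / f"{stem}_density.png")
    return report


def run_3d(stack_path, config: RunConfig, stem: str | None = None) -> dict:
    """Analyse one confocal stack and write the volume report and shell profile.

    Per-slice binarisation → ≥ ``min_slices_3d``-slice persistence
    filter → optional 2×2×2 max-pool → inscribed-ellipsoid
    decomposition → shell density profile and component volumes.
    """
    from .volume import maxpool_resize

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = stem or Path(stack_path).stem
    slices = read_stack(stack_path, config.pixel_size_um)
    vol = preprocess_stack(slices, config.z_spacing_um)
    vol = remove_spurious_3d(vol, config.min_slices_3d)
    if config.maxpool:
        vol = maxpool_resize(vol)
    if not vol.voxels.any():
        raise ValueError("segmentation produced an empty volume")
    core = fit_core_ellipsoid(vol)
    decomposition = decompose_3d(vol, core)
    shells = shell_profile_3d(decomposition, step=config.shell_step)
    volumes = measure_3d(decomposition)
    result = {
        **volumes,
        "core_semi_axes_um": list(core.semi_axes),
        "core_mean_radius_mm": core.mean_radius_um / 1000.0,
        "d_max_mm": float(
            shells.equivalent_distance_mm[np.nonzero(shells.density_total > 0)[0][-1]]
        )
        if shells.density_total.any()
        else 0.0,
    }
    (out / f"{stem}_report.json").write_text(json.dumps(result, indent=2))
    shells.to_dataframe().to_csv(out / f"{stem}_shells.csv", index=False)
    return result


def run_batch(
    manifest_path,
    config: RunConfig,
    control: str | None = None,
    treated: str | None = None,
):
    """Analyse a manifest of spheroid images grouped by condition.

    The manifest CSV has columns ``path, group, timepoint,
    pixel_size_um`` (timepoint "t0" rows are matched to same-group
    endpoint rows only via the group-level summary, not registered).
    Writes ``group_summary.csv`` (mean ± SEM per measurement and group)
    and, when control/treated group names are given,
    ``percent_change.csv``.
    """
    import pandas as pd

    manifest = pd.read_csv(manifest_path)
    for col in ("path", "group"):
        if col not in manifest.columns:
            raise ValueError(f"manifest lacks required column {col!r}")
    base = Path(manifest_path).parent
    reports: dict[str, list[MeasurementReport]] = {}
    for _, row in manifest.iterrows():
        cfg = dataclasses.replace(
            config,
            pixel_size_um=float(row.get("pixel_size_um", config.pixel_size_um)),
        )
        img_path = Path(row["path"])
        if not img_path.is_absolute():
            img_path = base / img_path
        image = read_image_2d(img_path, cfg.pixel_size_um)
        _, _, report = analyze_image_2d(image, cfg)
        reports.setdefault(str(row["group"]), []).append(report)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = group_summary(reports)
    summary.to_csv(out / "group_summary.csv", index=False)

    if control is not None and treated is not None:
        for name in (control, treated):
            if name not in reports:
                raise ValueError(f"unknown group reference {name!r}")
        rows = []
        for f in dataclasses.fields(MeasurementReport):
            vals_c = [getattr(r, f.name) for r in reports[control]]
            vals_t = [getattr(r, f.name) for r in reports[treated]]
            if any(v is None for v in vals_c + vals_t):
                continue
            try:
                pc = percent_change(vals_t, vals_c)
            except ValueError:
                continue
            rows.append(
                {
                    "measurement": f.name,
                    "control_mean": pc.mean_control,
                    "control_sem": pc.sem_control,
                    "treated_mean": pc.mean_treated,
                    "treated_sem": pc.sem_treated,
                    "kind": pc.kind,
                    "percent": pc.percent,
                }
            )
        pd.DataFrame(rows).to_csv(out / "percent_change.csv", index=False)
    return summary
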