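"""Published benchmark tables for validating group-comparison arithmetic.

Mean ± SEM measurements (mm² / mm / mm³) from a published lymphatic
endothelial-cell spheroid sprouting study: hTERT-HDLEC spheroids in
native collagen ± a broad-spectrum MMP inhibitor (RO-28-2653), in
pepsinized collagen ± an MMP2 inhibitor, and hMVEC-dly spheroids in
pepsinized collagen ± PMA stimulation.  Each row carries the printed
group means and, where the study printed one, the inhibition or
stimulation percentage, so that :func:`spheromet.metrics.percent_change`
can be validated against independently published arithmetic.

These numbers are *inputs* (reference data), not outputs of this
package: the underlying microscopy images are not publicly available,
so only the group-comparison arithmetic — not the raw measurements — can
be checked against them.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["BenchmarkRow", "BENCHMARK_TABLES"]


@dataclass(frozen=True)
class BenchmarkRow:
    table: str
    measurement: str
    t0_mean: float | None
    control_mean: float
    control_sem: float
    treated_mean: float
    treated_sem: float
    printed_percent: float | None  # None where the study printed "ns"
    kind: str  # "inhibition" or "stimulation" column of the source table


BENCHMARK_TABLES: tuple[BenchmarkRow, ...] = (
    # hTERT-HDLEC spheroids, native collagen, ± RO-28-2653 (24 h)
    BenchmarkRow("mmp_broad", "envelope_area", 0.0182, 0.2223, 0.0161, 0.0914, 0.00098, 59, "inhibition"),
    BenchmarkRow("mmp_broad", "total_cell_area", 0.0182, 0.0643, 0.0052, 0.0360, 0.0020, 44, "inhibition"),
    BenchmarkRow("mmp_broad", "d1", 0.0760, 0.3332, 0.0186, 0.2499, 0.0505, 25, "inhibition"),
    BenchmarkRow("mmp_broad", "d2", None, 0.2673, 0.0181, 0.1906, 0.0500, 29, "inhibition"),
    BenchmarkRow("mmp_broad", "core_area", 0.0182, 0.0144, 0.0011, 0.0102, 0.0005, 30, "inhibition"),
    BenchmarkRow("mmp_broad", "edging_area", None, 0.0249, 0.0026, 0.0222, 0.0012, None, "inhibition"),
    BenchmarkRow("mmp_broad", "detached_area", None, 0.0250, 0.0020, 0.0036, 0.0009, 86, "inhibition"),
    # hTERT-HDLEC spheroids, pepsinized collagen, ± MMP2 inhibitor (24 h)
    BenchmarkRow("mmp2", "envelope_area", 0.0149, 0.267, 0.008, 0.235, 0.01, 12, "inhibition"),
    BenchmarkRow("mmp2", "total_cell_area", 0.0149, 0.059, 0.004, 0.038, 0.002, 36, "inhibition"),
    BenchmarkRow("mmp2", "d1", 0.070, 0.342, 0.007, 0.324, 0.009, None, "inhibition"),
    BenchmarkRow("mmp2", "d2", None, 0.241, 0.009, 0.276, 0.01, 27, "inhibition"),
    BenchmarkRow("mmp2", "core_area", 0.0149, 0.018, 0.001, 0.007, 0.0004, 53, "inhibition"),
    BenchmarkRow("mmp2", "edging_area", None, 0.010, 0.001, 0.011, 0.001, None, "inhibition"),
    BenchmarkRow("mmp2", "detached_area", None, 0.031, 0.002, 0.027, 0.001, None, "inhibition"),
    # hMVEC-dly spheroids, pepsinized collagen, ± PMA (48 h)
    BenchmarkRow("pma", "envelope_area", 0.0126, 0.0184, 0.0011, 0.1459, 0.0138, 87, "stimulation"),
    BenchmarkRow("pma", "total_cell_area", 0.0126, 0.0127, 0.0006, 0.0386, 0.0035, 67, "stimulation"),
    BenchmarkRow("pma", "total_cell_volume", 0.0019, 0.0022, 0.0002, 0.0036, 0.0003, 39, "stimulation"),
    BenchmarkRow("pma", "d1", 0.0631, 0.1293, 0.0123, 0.3311, 0.0113, 61, "stimulation"),
    BenchmarkRow("pma", "d2", None, 0.0811, 0.0011, 0.2760, 0.0012, 71, "stimulation"),
    BenchmarkRow("pma", "core_area", 0.0126, 0.0074, 0.0004, 0.0096, 0.0004, None, "stimulation"),
    BenchmarkRow("pma", "core_volume", 0.0019, 0.0022, 0.0002, 0.0021, 0.0001, None, "stimulation"),
    BenchmarkRow("pma", "edging_area", None, 0.0053, 0.0004, 0.0291, 0.0038, 82, "stimulation"),
)
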