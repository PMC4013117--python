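"""Plotting of density and shell profiles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

_COLOURS = {"core": "tab:blue", "edging": "tab:green", "detached": "tab:red"}


def plot_density_profile(profile, path=None, ax=None, smooth: int = 0):
    """Plot per-component density curves against distance (mm).

    ``smooth`` applies a centred moving average of that window (display
    only; measurements always use the raw curves).
    """
    import numpy as np

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    x = profile.radii_mm if hasattr(profile, "radii_mm") else profile.equivalent_distance_mm
    for name, colour in _COLOURS.items():
        y = profile.density(name)
        if smooth > 1:
            kernel = np.ones(smooth) / smooth
            y = np.convolve(y, kernel, mode="same")
        ax.plot(x, y, color=colour, label=name)
    ax.set_xlabel("distance from spheroid centre (mm)")
    ax.set_ylabel("cell density $N_i/P_i$")
    ax.set_ylim(-0.02, 1.05)
    ax.legend(frameon=False, fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
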