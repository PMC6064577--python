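"""Quick-look figures: greyness histograms, F-vs-B lines, audit maps."""

from __future__ import annotations

import numpy as np

from canopyhp.image_analysis import GreynessHistogram, MisclassificationMap

__all__ = [
    "plot_greyness_histogram",
    "plot_grey_fraction_vs_border",
    "plot_misclassification",
]


def plot_greyness_histogram(
    hist: GreynessHistogram, bounds: tuple[int, int] | None = None, ax=None
):
    """Pixel fraction per digital number, linear y-scale, optional bounds."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.bar(np.arange(256), hist.counts / hist.total, width=1.0, color="0.4")
    if bounds is not None:
        for bound in bounds:
            ax.axvline(bound, color="tab:red", lw=1, ls="--")
    ax.set_xlabel("digital number")
    ax.set_ylabel("pixel fraction")
    return ax


def plot_grey_fraction_vs_border(border, grey_fraction, fit=None, ax=None):
    """Grey-pixel fraction against SCB length per unit area."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    border = np.asarray(border, dtype=float)
    ax.plot(border, grey_fraction, "o", color="k", ms=4)
    if fit is not None:
        grid = np.linspace(0.0, border.max() * 1.05, 50)
        ax.plot(grid, fit.inverse_sharpness * grid + fit.stray_grey, "-", lw=1)
        ax.set_title(
            f"1/S = {fit.inverse_sharpness:.3g} mm, G = {fit.stray_grey:.2g}, "
            f"r$^2$ = {fit.r2:.3f}"
        )
    ax.set_xlabel("SCB length per unit area (mm mm$^{-2}$)")
    ax.set_ylabel("grey-pixel fraction")
    return ax


def plot_misclassification(audit: MisclassificationMap, ax=None):
    """White/black/red/blue misclassification map."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.imshow(audit.to_rgb(), interpolation="nearest")
    ax.set_axis_off()
    return ax
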