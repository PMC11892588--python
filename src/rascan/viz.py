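"""Trend plots of the RAS series with detected change points and thresholds."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .ras_core import RASSeries

__all__ = ["plot_trend"]


def plot_trend(series_by_chrom: dict[str, RASSeries],
               peaks_by_chrom: dict[str, list] | None = None,
               magnitude_threshold: float | None = None,
               path=None):
    """One panel per chromosome: RAS vs position, peaks and thresholds.

    Red dotted vertical lines mark detected change-point peaks; the blue
    dotted horizontal line marks the magnitude threshold.  Saves SVG and/or
    PNG when ``path`` is given (suffix decides; no suffix writes both).
    """
    chroms = list(series_by_chrom)
    fig, axes = plt.subplots(len(chroms), 1,
                             figsize=(9, 2.8 * len(chroms)), squeeze=False)
    for ax, chrom in zip(axes[:, 0], chroms):
        s = series_by_chrom[chrom]
        mb = s.position_bp / 1e6
        ax.plot(mb, s.ras, lw=0.9, color="0.25")
        for pos, ras_val, _p in (peaks_by_chrom or {}).get(chrom, []):
            ax.axvline(mb[pos], color="red", ls=":", lw=1.0)
            ax.plot(mb[pos], ras_val, "v", color="red", ms=5)
        if magnitude_threshold is not None and np.isfinite(magnitude_threshold):
            ax.axhline(magnitude_threshold, color="blue", ls=":", lw=1.0)
        ax.set_ylabel("RAS")
        ax.set_title(f"chromosome {chrom}", fontsize=10)
    axes[-1, 0].set_xlabel("position (Mb)")
    fig.tight_layout()
    if path is not None:
        path = str(path)
        if path.endswith((".svg", ".png")):
            fig.savefig(path, dpi=150)
        else:
            fig.savefig(path + ".svg")
            fig.savefig(path + ".png", dpi=150)
        plt.close(fig)
        return None
    return fig
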