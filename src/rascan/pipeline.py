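"""End-to-end orchestration: RAS series -> peak detection -> regions.

Multi-chromosome input is scanned independently per chromosome and the
results concatenated.  Used by the calibration loop, the CLI and the
acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import CovariateMatrix, GenotypeDataset, PhenotypeVector
from .peak_detect import DetectedRegion, detect_peaks, form_regions
from .ras_core import RASSeries, ScanConfig, ras_series

__all__ = ["ScanResult", "scan"]


@dataclass
class ScanResult:
    """Regions plus the per-chromosome series and raw peaks behind them."""

    regions: list[DetectedRegion]
    series: dict[str, RASSeries]
    peaks: dict[str, list[tuple[int, float, float]]]


def scan(G: GenotypeDataset, y: PhenotypeVector,
         X: CovariateMatrix | None = None,
         config: ScanConfig | None = None,
         magnitude_threshold: float | None = None) -> ScanResult:
    """Run the full RAS pipeline on every chromosome of ``G``.

    ``magnitude_threshold`` overrides ``config.magnitude_threshold``; pass
    ``-inf`` to disable magnitude filtering (e.g. during calibration).
    """
    config = config or ScanConfig()
    X = X or CovariateMatrix.empty(G.n)
    thr = (magnitude_threshold if magnitude_threshold is not None
           else config.magnitude_threshold)
    if thr is None:
        raise ValueError(
            "no magnitude threshold: calibrate first or set one explicitly")

    regions: list[DetectedRegion] = []
    series_by: dict[str, RASSeries] = {}
    peaks_by: dict[str, list] = {}
    for chrom in pd.unique(G.chromosome):
        Gc = G.subset_snps(np.flatnonzero(G.chromosome == chrom))
        series = ras_series(Gc, y, X, config=config)
        peaks = detect_peaks(series, config)
        series_by[str(chrom)] = series
        peaks_by[str(chrom)] = peaks
        regions.extend(form_regions(peaks, series, Gc, thr))
    return ScanResult(regions=regions, series=series_by, peaks=peaks_by)
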