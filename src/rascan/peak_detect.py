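"""Peak detection on the RAS series and conversion of peaks into regions.

Associated regions show up as peaks in the pivotal-SNP RAS series.  A
sliding window walks the series; within each window a permutation CUSUM test
asks whether a change point is present, the most likely change point is
located, and the peak shape is verified by requiring a significantly
positive slope on the left of the change point and a significantly negative
slope on the right.  Verified peaks above a preset magnitude threshold are
reported as regions spanning the RAS-optimal window of the apex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeDataset
from .ras_core import RASSeries, ScanConfig

__all__ = [
    "ChangePointResult",
    "DetectedRegion",
    "changepoint_test",
    "slope_check",
    "detect_peaks",
    "form_regions",
    "regions_to_bed",
    "regions_to_tsv",
]

MIN_SEGMENT = 3     # points required on each side of a change point
APEX_RADIUS = 5     # series points searched around a change point for the apex


@dataclass
class ChangePointResult:
    """Permutation test outcome for one sliding window."""

    p_value: float
    cp_offset: int    # 0-based offset of the first point right of the change
    statistic: float


@dataclass
class DetectedRegion:
    """A chromosome interval claimed as associated (1-based, closed)."""

    chromosome: str
    start_bp: int
    end_bp: int
    peak_pivotal_index: int   # 1-based SNP index of the apex pivotal SNP
    peak_ras: float
    t_star: int
    peak_snp_id: str = ""
    cp_p_value: float = float("nan")

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("region start exceeds end")

    @property
    def interval(self) -> tuple[int, int]:
        return (int(self.start_bp), int(self.end_bp))


# ---------------------------------------------------------------------------
# change-point test (max standardized mean-difference CUSUM, permutation p)
# ---------------------------------------------------------------------------

def _cusum_stats(values: np.ndarray, min_segment: int) -> np.ndarray:
    """|mean-left - mean-right| / (s * sqrt(1/k + 1/(W-k))) for each split.

    ``values`` may be (W,) or (B, W) for batched permutations; the window-
    wide sample SD s standardizes so a constant window scores 0 and a
    noiseless step stays finite.  Split k = size of the left segment, k in
    [min_segment, W - min_segment].
    """
    v = np.atleast_2d(values).astype(float)
    B, W = v.shape
    ks = np.arange(min_segment, W - min_segment + 1)
    cum = np.cumsum(v, axis=1)
    total = cum[:, -1:]
    mean_l = cum[:, ks - 1] / ks
    mean_r = (total - cum[:, ks - 1]) / (W - ks)
    s = v.std(axis=1, ddof=1, keepdims=True)
    scale = np.sqrt(1.0 / ks + 1.0 / (W - ks))
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.abs(mean_l - mean_r) / (s * scale)
    return np.where(s > 0, stat, 0.0)


def changepoint_test(window_values: np.ndarray, n_permutations: int = 200,
                     seed=0, min_segment: int = MIN_SEGMENT
                     ) -> ChangePointResult:
    """Test for a single change point in ``window_values``.

    The statistic is the maximum over interior splits of the standardized
    difference in segment means; its null distribution is obtained by
    shuffling the window values with a seeded generator.  The p-value uses
    the add-one permutation convention (1 + #{perm >= obs}) / (1 + B), so a
    clean step scores 1/(1+B).
    """
    v = np.asarray(window_values, dtype=float)
    W = len(v)
    if W < 2 * min_segment:
        raise ValueError(f"window of {W} points is too short "
                         f"(need >= {2 * min_segment})")
    stats_obs = _cusum_stats(v, min_segment)[0]
    offset = int(np.argmax(stats_obs)) + min_segment
    observed = float(stats_obs.max())
    if observed == 0.0:  # constant window
        return ChangePointResult(p_value=1.0, cp_offset=offset, statistic=0.0)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(v, (n_permutations, 1)), axis=1)
    null_max = _cusum_stats(perms, min_segment).max(axis=1)
    p = (1.0 + np.count_nonzero(null_max >= observed)) / (1.0 + n_permutations)
    return ChangePointResult(p_value=float(p), cp_offset=offset,
                             statistic=observed)


def slope_check(window_values: np.ndarray, cp_offset: int,
                slope_alpha: float = 0.05,
                min_segment: int = MIN_SEGMENT) -> bool:
    """Verify the change point is a peak apex by one-sided slope tests.

    Ordinary least-squares lines of value on within-window index are fitted
    on [start..cp] and [cp..end]; both the left-slope > 0 and right-slope < 0
    one-sided t tests must reject at ``slope_alpha``.  Degenerate segments
    (too short, or zero residual variation making the test ill-posed) fail.
    """
    v = np.asarray(window_values, dtype=float)
    left = v[: cp_offset + 1]
    right = v[cp_offset:]
    if len(left) < min_segment or len(right) < min_segment:
        return False

    def one_sided_p(seg: np.ndarray, direction: int) -> float:
        x = np.arange(len(seg), dtype=float)
        slope, _, _, _, stderr = stats.linregress(x, seg)
        if not np.isfinite(stderr) or stderr == 0:
            return 1.0
        t = direction * slope / stderr
        return float(stats.t.sf(t, len(seg) - 2))

    return (one_sided_p(left, +1) < slope_alpha
            and one_sided_p(right, -1) < slope_alpha)


# ---------------------------------------------------------------------------
# sliding-window scan over the series
# ---------------------------------------------------------------------------

def _climb_to_apex(ras: np.ndarray, pos: int, lo_bound: int,
                   hi_bound: int, radius: int = APEX_RADIUS) -> int:
    """Nearest local maximum: repeated +/- radius argmax steps from ``pos``.

    The CUSUM change point sits on a flank of the peak; hill-climbing in
    APEX_RADIUS-sized steps (strict improvement only, bounded to the current
    window) lands on the apex even when the elevated stretch is wider than
    one step.  Deterministic: ties stop the climb.
    """
    while True:
        lo = max(pos - radius, lo_bound)
        hi = min(pos + radius + 1, hi_bound)
        cand = lo + int(np.argmax(ras[lo:hi]))
        if cand == pos or ras[cand] <= ras[pos]:
            return pos
        pos = cand


def detect_peaks(series: RASSeries, config: ScanConfig | None = None
                 ) -> list[tuple[int, float, float]]:
    """Scan the RAS series for verified peaks.

    Windows of ``config.cp_window`` pivotal points slide along the series.
    When the change-point test rejects at ``cp_alpha``, the candidate apex —
    the local maximum reached by hill-climbing from the change point in
    APEX_RADIUS-sized steps within the window — is slope-verified (significantly rising on its left, falling on its
    right, within the window); on success a peak is recorded at the apex and
    the next window starts at the change point, otherwise the window
    advances by round((1 - cp_overlap) * cp_window) (at least 1).  The CUSUM
    change point marks the boundary of an elevated stretch, so the slope
    check is anchored at the apex, the point actually claimed as the peak.  The final partial
    window is evaluated while it holds at least 2 * MIN_SEGMENT points.
    Duplicate apexes are merged keeping the smallest p-value.  Permutations
    are seeded from (config.seed, window start), so the scan is
    deterministic.

    Returns [(apex position in the series, apex ras, change-point p)].
    """
    config = config or ScanConfig()
    L = len(series)
    W = config.cp_window
    if L < W:
        raise ValueError(f"series of {L} points shorter than cp_window={W}")
    shift = max(int(round((1.0 - config.cp_overlap) * W)), 1)
    peaks: dict[int, tuple[float, float]] = {}

    start = 0
    while start < L:
        window = series.ras[start: start + W]
        if len(window) < 2 * MIN_SEGMENT:
            break
        res = changepoint_test(
            window, n_permutations=config.n_cp_permutations,
            seed=np.random.SeedSequence(
                [int(config.seed) & 0x7FFFFFFF, 202, start]),
        )
        cp_abs = start + res.cp_offset
        apex = _climb_to_apex(series.ras, cp_abs, start, start + len(window))
        accepted = (res.p_value < config.cp_alpha
                    and slope_check(window, apex - start, config.slope_alpha))
        if accepted:
            prev = peaks.get(apex)
            if prev is None or res.p_value < prev[1]:
                peaks[apex] = (float(series.ras[apex]), res.p_value)
            start = cp_abs  # change point seeds the next window
        else:
            start += shift
    return [(pos, peaks[pos][0], peaks[pos][1]) for pos in sorted(peaks)]


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

def form_regions(peaks: list[tuple[int, float, float]], series: RASSeries,
                 G: GenotypeDataset, magnitude_threshold: float
                 ) -> list[DetectedRegion]:
    """Filter peaks by magnitude and expand survivors into bp regions.

    A surviving peak at pivotal SNP j* (1-based) with optimal half-width t*
    spans SNP indices [max(j*-t*, 1), min(j*+t*, p)], reported as the closed
    bp interval of those SNPs.  Overlapping regions are merged (interval
    union, keeping the larger peak_ras as the region's score).
    """
    p = G.p
    raw: list[DetectedRegion] = []
    for pos, ras_val, p_val in peaks:
        if ras_val < magnitude_threshold:
            continue
        j1 = int(series.pivotal_index[pos])        # 1-based
        t = int(series.t_star[pos])
        lo1, hi1 = max(j1 - t, 1), min(j1 + t, p)
        chrom = (str(series.chromosome[pos])
                 if series.chromosome is not None else "1")
        raw.append(DetectedRegion(
            chromosome=chrom,
            start_bp=int(G.position_bp[lo1 - 1]),
            end_bp=int(G.position_bp[hi1 - 1]),
            peak_pivotal_index=j1,
            peak_ras=float(ras_val),
            t_star=t,
            peak_snp_id=(str(series.snp_id[pos])
                         if series.snp_id is not None else ""),
            cp_p_value=float(p_val),
        ))
    return merge_regions(raw)


def merge_regions(regions: list[DetectedRegion]) -> list[DetectedRegion]:
    """Union of overlapping closed intervals per chromosome; the merged
    region keeps the peak metadata of its largest peak_ras member."""
    out: list[DetectedRegion] = []
    by_chrom: dict[str, list[DetectedRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chromosome, []).append(r)
    for chrom in by_chrom:
        regs = sorted(by_chrom[chrom], key=lambda r: (r.start_bp, r.end_bp))
        cur = regs[0]
        for r in regs[1:]:
            if r.start_bp <= cur.end_bp:  # closed intervals: touching merges
                best = cur if cur.peak_ras >= r.peak_ras else r
                cur = DetectedRegion(
                    chromosome=chrom,
                    start_bp=cur.start_bp,
                    end_bp=max(cur.end_bp, r.end_bp),
                    peak_pivotal_index=best.peak_pivotal_index,
                    peak_ras=best.peak_ras,
                    t_star=best.t_star,
                    peak_snp_id=best.peak_snp_id,
                    cp_p_value=best.cp_p_value,
                )
            else:
                out.append(cur)
                cur = r
        out.append(cur)
    out.sort(key=lambda r: (r.chromosome, r.start_bp))
    return out


def regions_to_bed(regions: list[DetectedRegion], path) -> None:
    """BED export: 0-based half-open, name = peak SNP id, score = peak RAS."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chromosome}\t{r.start_bp - 1}\t{r.end_bp}\t"
                     f"{r.peak_snp_id}\t{r.peak_ras:.6g}\n")


def regions_to_tsv(regions: list[DetectedRegion], path) -> None:
    """Rich TSV export: 1-based closed intervals plus peak metadata."""
    df = pd.DataFrame([{
        "chromosome": r.chromosome,
        "start_bp": r.start_bp,
        "end_bp": r.end_bp,
        "peak_snp_id": r.peak_snp_id,
        "peak_pivotal_index": r.peak_pivotal_index,
        "peak_ras": r.peak_ras,
        "t_star": r.t_star,
        "cp_p_value": r.cp_p_value,
    } for r in regions],
        columns=["chromosome", "start_bp", "end_bp", "peak_snp_id",
                 "peak_pivotal_index", "peak_ras", "t_star", "cp_p_value"])
    df.to_csv(path, sep="\t", index=False)
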