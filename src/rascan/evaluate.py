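"""Scoring detections against ground truth; type I error, power, FPR-A.

A true region counts as identified if it overlaps (closed bp intervals) any
detected region; a detected region overlapping no true region is a false
positive.  Power is the probability of identifying all M true regions in a
run; the type I error (null runs) and FPR-A (alternative runs) are the
per-run probabilities of reporting at least one false-positive region.
Rates carry the binomial standard error sqrt(rate * (1 - rate) / n_runs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "RunScore",
    "RateEstimate",
    "regions_overlap",
    "score_run",
    "empirical_rates",
    "rates_table",
]


@dataclass
class RunScore:
    """Detection outcome of one simulation run."""

    all_regions_detected: bool
    n_true_detected: int
    n_false_positive_regions: int

    @property
    def any_false_positive(self) -> bool:
        return self.n_false_positive_regions >= 1


@dataclass
class RateEstimate:
    """A binomial rate with its standard error."""

    rate: float
    se: float
    n_runs: int


def _interval(r) -> tuple[int, int]:
    """Accept (start, end) tuples or objects with an ``interval`` attr."""
    iv = getattr(r, "interval", r)
    start, end = int(iv[0]), int(iv[1])
    if start > end:
        raise ValueError(f"malformed interval {iv!r}: start > end")
    return start, end


def regions_overlap(a, b) -> bool:
    """Closed-interval overlap: shared endpoints count."""
    a0, a1 = _interval(a)
    b0, b1 = _interval(b)
    return max(a0, b0) <= min(a1, b1)


def score_run(true_regions, detected_regions) -> RunScore:
    """Overlap-score one run; under the null every detection is a false
    positive.  Symmetric in the list order of truths and detections."""
    truths = [_interval(r) for r in true_regions]
    dets = [_interval(r) for r in detected_regions]
    n_true_detected = sum(
        any(regions_overlap(t, d) for d in dets) for t in truths)
    n_fp = sum(not any(regions_overlap(d, t) for t in truths) for d in dets)
    return RunScore(
        all_regions_detected=(len(truths) > 0
                              and n_true_detected == len(truths)),
        n_true_detected=n_true_detected,
        n_false_positive_regions=n_fp,
    )


def empirical_rates(scores: list[RunScore], which: str) -> RateEstimate:
    """Aggregate run scores into a rate with binomial SE.

    ``which``: 'typeI' (null runs, any false positive), 'power' (all true
    regions detected), or 'fpra' (alternative runs, any false positive).
    """
    if not scores:
        raise ValueError("need at least one run")
    if which in ("typeI", "fpra"):
        hits = sum(s.any_false_positive for s in scores)
    elif which == "power":
        hits = sum(s.all_regions_detected for s in scores)
    else:
        raise ValueError(f"unknown metric {which!r}")
    n = len(scores)
    rate = hits / n
    se = math.sqrt(rate * (1.0 - rate) / n)
    return RateEstimate(rate=rate, se=se, n_runs=n)


def rates_table(named_scores: dict[str, tuple[list[RunScore], str]]
                ) -> pd.DataFrame:
    """Tabulate (setting -> (scores, metric)) as columns
    setting/metric/rate/se/n_runs, ready for TSV export."""
    rows = []
    for setting, (scores, metric) in named_scores.items():
        est = empirical_rates(scores, metric)
        rows.append({"setting": setting, "metric": metric,
                     "rate": est.rate, "se": est.se, "n_runs": est.n_runs})
    return pd.DataFrame(rows,
                        columns=["setting", "metric", "rate", "se", "n_runs"])
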