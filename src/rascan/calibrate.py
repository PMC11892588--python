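"""Magnitude-threshold calibration for chromosome-wide type I error control.

The final peak filter of the pipeline is a magnitude threshold on the RAS of
a verified peak.  It is calibrated on parametric null simulations: draw a
phenotype from the null model on the actual genotypes, run the full pipeline
with magnitude filtering disabled, record the maximum surviving peak RAS
(-inf when no peak passes the change-point and slope stages), and take the
empirical (1 - alpha) quantile of those maxima — the smallest grid value t
with fraction{max >= t} <= alpha.  Reporting only peaks above t then keeps
the probability of claiming any region under the global null at or below
alpha over the whole chromosome.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import logit

from .genotype_io import CovariateMatrix, GenotypeDataset, PhenotypeVector
from .pipeline import scan
from .ras_core import ScanConfig

logger = logging.getLogger("rascan")

__all__ = [
    "CalibrationResult",
    "simulate_null_phenotype",
    "threshold_from_maxima",
    "calibrate_threshold",
    "null_max_statistics",
    "null_max_statistics_permuted",
    "validate_threshold",
]


@dataclass
class CalibrationResult:
    """Calibrated threshold and the null maxima it was derived from."""

    threshold: float
    target_level: float
    empirical_fwer: float
    n_null_runs: int
    null_peak_maxima: np.ndarray

    def __post_init__(self) -> None:
        self.null_peak_maxima = np.asarray(self.null_peak_maxima, dtype=float)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "threshold": self.threshold,
                "target_level": self.target_level,
                "empirical_fwer": self.empirical_fwer,
                "n_null_runs": self.n_null_runs,
                "null_peak_maxima": [
                    None if not np.isfinite(v) else float(v)
                    for v in self.null_peak_maxima],
            }, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CalibrationResult":
        with open(path) as fh:
            d = json.load(fh)
        maxima = np.array([-np.inf if v is None else v
                           for v in d["null_peak_maxima"]])
        return cls(threshold=d["threshold"], target_level=d["target_level"],
                   empirical_fwer=d["empirical_fwer"],
                   n_null_runs=d["n_null_runs"], null_peak_maxima=maxima)


def simulate_null_phenotype(G: GenotypeDataset, X: CovariateMatrix | None,
                            family: str, seed,
                            case_fraction: float = 0.2) -> PhenotypeVector:
    """Phenotypes under the global null, independent of G and X.

    Gaussian: y ~ N(0, 1) (alpha0 = 0, sigma = 1).  Binomial:
    Bernoulli(case_fraction), i.e. intercept alpha0 = logit(case_fraction).
    """
    rng = np.random.default_rng(seed)
    if family == "gaussian":
        return PhenotypeVector(values=rng.standard_normal(G.n),
                               family="gaussian")
    if family == "binomial":
        # alpha0 = logit(case_fraction) makes P(y=1) exactly case_fraction
        _ = float(logit(case_fraction))
        y = (rng.random(G.n) < case_fraction).astype(float)
        return PhenotypeVector(values=y, family="binomial")
    raise ValueError(f"unknown family {family!r}")


def threshold_from_maxima(maxima: np.ndarray, target_level: float) -> float:
    """Smallest value t with fraction{maxima >= t} <= target_level.

    Searches the observed maxima as the candidate grid; if no run produced a
    peak the threshold is 0, and if even the largest maximum is too frequent
    the threshold sits just above it.
    """
    maxima = np.asarray(maxima, dtype=float)
    B = len(maxima)
    finite = np.sort(maxima[np.isfinite(maxima)])
    if finite.size == 0:
        return 0.0
    for v in np.unique(finite):
        if np.count_nonzero(maxima >= v) / B <= target_level:
            return float(v)
    return float(np.nextafter(finite[-1], np.inf))


def _run_seed(master: int, label: int, run: int) -> int:
    """Derive a stable sub-2^31 integer seed for one null run."""
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF, label, run])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def null_max_statistics(G: GenotypeDataset, X: CovariateMatrix | None,
                        family: str, config: ScanConfig, n_runs: int,
                        seed_label: int = 1000,
                        case_fraction: float = 0.2) -> np.ndarray:
    """Maximum verified-peak RAS of each of ``n_runs`` null pipeline runs.

    Each run draws a fresh null phenotype (seeded from ``config.seed``,
    ``seed_label`` and the run index), runs the full pipeline with magnitude
    filtering disabled, and records the largest peak RAS (-inf if no peak
    survives the change-point and slope stages).
    """
    X = X or CovariateMatrix.empty(G.n)
    maxima = np.empty(n_runs)
    for b in range(n_runs):
        s = _run_seed(config.seed, seed_label, b)
        y = simulate_null_phenotype(G, X, family, seed=s,
                                    case_fraction=case_fraction)
        cfg = replace(config, seed=_run_seed(config.seed, seed_label + 1, b))
        result = scan(G, y, X, cfg, magnitude_threshold=-np.inf)
        peak_ras = [r.peak_ras for r in result.regions]
        maxima[b] = max(peak_ras) if peak_ras else -np.inf
    return maxima


def null_max_statistics_permuted(G: GenotypeDataset, y: PhenotypeVector,
                                 X: CovariateMatrix | None,
                                 config: ScanConfig, n_runs: int,
                                 seed_label: int = 3000) -> np.ndarray:
    """Permutation null for real data: shuffle genotype rows against the
    intact (y, X) pairs.  Caveat: this also breaks any genotype-covariate
    dependence such as population structure."""
    X = X or CovariateMatrix.empty(G.n)
    maxima = np.empty(n_runs)
    for b in range(n_runs):
        rng = np.random.default_rng(_run_seed(config.seed, seed_label, b))
        Gp = G.subset_samples(rng.permutation(G.n))
        cfg = replace(config, seed=_run_seed(config.seed, seed_label + 1, b))
        result = scan(Gp, y, X, cfg, magnitude_threshold=-np.inf)
        peak_ras = [r.peak_ras for r in result.regions]
        maxima[b] = max(peak_ras) if peak_ras else -np.inf
    return maxima


def calibrate_threshold(G: GenotypeDataset, X: CovariateMatrix | None,
                        family: str, config: ScanConfig,
                        target_level: float = 0.05,
                        n_null_runs: int = 200,
                        case_fraction: float = 0.2) -> CalibrationResult:
    """Calibrate the magnitude threshold on parametric null simulations.

    The change-point and slope levels stay fixed; only the magnitude
    threshold is tuned, as the empirical (1 - target_level) quantile of the
    per-run null maxima.  ``empirical_fwer`` is the fraction of calibration
    runs at or above the returned threshold (<= target_level by
    construction).
    """
    if n_null_runs < 20:
        raise ValueError("need at least 20 null runs to calibrate")
    if n_null_runs < 1.0 / target_level:
        logger.warning(
            "only %d null runs for target level %g; the quantile estimate "
            "is unstable", n_null_runs, target_level)
    maxima = null_max_statistics(G, X, family, config, n_null_runs,
                                 seed_label=1000, case_fraction=case_fraction)
    thr = threshold_from_maxima(maxima, target_level)
    fwer = float(np.count_nonzero(maxima >= thr) / n_null_runs)
    return CalibrationResult(threshold=thr, target_level=target_level,
                             empirical_fwer=fwer, n_null_runs=n_null_runs,
                             null_peak_maxima=maxima)


def validate_threshold(G: GenotypeDataset, X: CovariateMatrix | None,
                       family: str, config: ScanConfig, threshold: float,
                       n_runs: int = 200, seed_label: int = 2000,
                       case_fraction: float = 0.2) -> float:
    """Held-out FWER check: fraction of fresh null runs reporting a region."""
    maxima = null_max_statistics(G, X, family, config, n_runs,
                                 seed_label=seed_label,
                                 case_fraction=case_fraction)
    return float(np.count_nonzero(maxima >= threshold) / n_runs)
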