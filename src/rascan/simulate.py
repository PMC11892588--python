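"""LD-structured synthetic genotypes and phenotypes for the simulation study.

Genotypes: each sample carries a latent stationary AR(1) Gaussian sequence
(corr(Z_j, Z_{j+1}) = ld_rho) thresholded at the standard-normal quantiles of
the Hardy–Weinberg class probabilities (1-f)^2, 2f(1-f), f^2 of SNP j's MAF
f, producing 0/1/2 minor-allele dosages with tunable local LD.  MAFs follow
a two-component mixture — a fraction of low-frequency SNPs from
Uniform(0.01, 0.05) and the rest common from Uniform(0.05, 0.5) — matching
the 20%/80% low-frequency/common split of typical genotyping-array data.

Phenotypes: the null models are y = alpha0 + eps, eps ~ N(0, sigma^2)
(gaussian, alpha0 = 0) and logit P(y=1) = alpha0 (binomial, alpha0 set to the
logit of the target case fraction).  Alternatives add beta'G_i with
beta_j = +/- s * c * |log10 MAF_j| inside M signal regions of T_sig
consecutive SNPs, s ~ Bernoulli(q), sign equiprobable, zero elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit, logit

from .genotype_io import GenotypeDataset, PhenotypeVector

__all__ = [
    "SimConfig",
    "TrueSignal",
    "simulate_genotypes",
    "make_beta",
    "simulate_phenotype",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the simulation conditions of the method's evaluation:
    ~3 kb SNP spacing so a T_sig = 100 signal region spans ~0.3 Mb, a
    20%/80% low-frequency/common MAF mixture, sigma = 1 noise, 0.2/0.8
    case/control balance, and signal strength c = 0.04 (continuous scale).
    """

    n: int = 1000
    p: int = 500
    ld_rho: float = 0.9
    fraction_low: float = 0.2           # MAF ~ Uniform(0.01, 0.05)
    spacing_bp: int = 3000
    M: int = 1
    T_sig: int = 100
    q: float = 1.0
    c: float = 0.04
    sigma: float = 1.0
    case_fraction: float = 0.2
    family: str = "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must lie in [0, 1)")
        if not 0 <= self.q <= 1:
            raise ValueError("q must lie in [0, 1]")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must lie in (0, 1)")
        if self.M * self.T_sig > self.p:
            raise ValueError("M * T_sig exceeds the number of SNPs")
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class TrueSignal:
    """Ground-truth effect vector and the signal regions that carry it."""

    beta: np.ndarray
    region_starts: np.ndarray            # 0-based SNP index of each region
    regions_bp: list                     # closed (start_bp, end_bp) intervals

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.region_starts = np.asarray(self.region_starts, dtype=int)


def _draw_mafs(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    low = rng.random(cfg.p) < cfg.fraction_low
    maf = np.empty(cfg.p)
    maf[low] = rng.uniform(0.01, 0.05, low.sum())
    maf[~low] = rng.uniform(0.05, 0.5, (~low).sum())
    return maf


def simulate_genotypes(cfg: SimConfig,
                       mafs: np.ndarray | None = None) -> GenotypeDataset:
    """Draw an LD-structured n x p dosage matrix; reproducible under seed.

    SNP positions are ``spacing_bp * (j+1)`` on chromosome "1".  The latent
    AR(1) uses the stationary recursion Z_{j+1} = rho Z_j + sqrt(1-rho^2) e.
    ``mafs`` overrides the mixture draw with fixed per-SNP target MAFs.
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(cfg.seed) & 0x7FFFFFFF, 11]))
    maf = np.asarray(mafs, dtype=float) if mafs is not None \
        else _draw_mafs(cfg, rng)
    if len(maf) != cfg.p:
        raise ValueError("mafs length must equal cfg.p")
    eps = rng.standard_normal((cfg.n, cfg.p))
    Z = np.empty((cfg.n, cfg.p))
    Z[:, 0] = eps[:, 0]
    rho, scale = cfg.ld_rho, np.sqrt(1.0 - cfg.ld_rho ** 2)
    for j in range(1, cfg.p):
        Z[:, j] = rho * Z[:, j - 1] + scale * eps[:, j]
    # Hardy–Weinberg class boundaries on the latent scale
    p0 = (1.0 - maf) ** 2
    c1 = stats.norm.ppf(p0)
    c2 = stats.norm.ppf(p0 + 2.0 * maf * (1.0 - maf))
    dosages = (Z > c1).astype(float) + (Z > c2)
    return GenotypeDataset(
        dosages=dosages,
        sample_ids=np.array([f"S{i:06d}" for i in range(cfg.n)], dtype=object),
        snp_ids=np.array([f"snp{j + 1:06d}" for j in range(cfg.p)], dtype=object),
        chromosome=np.array(["1"] * cfg.p, dtype=object),
        position_bp=cfg.spacing_bp * np.arange(1, cfg.p + 1),
    )


def make_beta(mafs: np.ndarray, cfg: SimConfig,
              positions_bp: np.ndarray | None = None) -> TrueSignal:
    """Build the sparse effect vector beta_j = +/- s * c * |log10 MAF_j|.

    M region starts are drawn uniformly at random with pairwise start
    separation >= 2 * T_sig SNPs (so regions never overlap); within a
    region each SNP is causal independently with probability q, with an
    equiprobable random sign.  Reproducible under cfg.seed.
    """
    p = len(mafs)
    if cfg.M * cfg.T_sig > p:
        raise ValueError("cannot place M regions of T_sig SNPs in p SNPs")
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(cfg.seed) & 0x7FFFFFFF, 22]))
    starts: list[int] = []
    max_start = p - cfg.T_sig
    for _ in range(10000):
        cand = int(rng.integers(0, max_start + 1))
        if all(abs(cand - s) >= 2 * cfg.T_sig for s in starts):
            starts.append(cand)
            if len(starts) == cfg.M:
                break
    if len(starts) < cfg.M:
        raise ValueError(
            f"could not place {cfg.M} regions of {cfg.T_sig} SNPs with "
            f"separation {2 * cfg.T_sig} among {p} SNPs")
    starts = sorted(starts)

    beta = np.zeros(p)
    for s0 in starts:
        idx = np.arange(s0, s0 + cfg.T_sig)
        causal = rng.random(cfg.T_sig) < cfg.q
        signs = rng.choice([-1.0, 1.0], size=cfg.T_sig)
        beta[idx] = np.where(
            causal, signs * cfg.c * np.abs(np.log10(mafs[idx])), 0.0)

    if positions_bp is None:
        positions_bp = np.arange(1, p + 1)
    regions_bp = [(int(positions_bp[s0]), int(positions_bp[s0 + cfg.T_sig - 1]))
                  for s0 in starts]
    return TrueSignal(beta=beta, region_starts=np.asarray(starts),
                      regions_bp=regions_bp)


def _solve_alpha0(lin: np.ndarray, target: float) -> float:
    """Intercept making mean expit(alpha0 + lin) equal the target fraction."""
    def f(a):
        return float(np.mean(expit(a + lin))) - target
    lo, hi = -30.0, 30.0
    return brentq(f, lo, hi, xtol=1e-10)


def simulate_phenotype(G: GenotypeDataset, signal: TrueSignal | None,
                       cfg: SimConfig, seed=None) -> PhenotypeVector:
    """Draw phenotypes from the (null or alternative) generating model.

    Gaussian: y_i = beta'G_i + N(0, sigma^2) (alpha0 = 0).  Binomial:
    Bernoulli(expit(alpha0 + beta'G_i)) with alpha0 solved by root finding
    so the sample-average event probability equals ``cfg.case_fraction``
    (for beta = 0 this reduces to alpha0 = logit(case_fraction) exactly).
    ``signal=None`` means the global null beta = 0.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed) & 0x7FFFFFFF, 33])
        if seed is None else seed)
    lin = (G.dosages @ signal.beta if signal is not None
           else np.zeros(G.n))
    if cfg.family == "gaussian":
        y = lin + cfg.sigma * rng.standard_normal(G.n)
        return PhenotypeVector(values=y, family="gaussian")
    if signal is None or not np.any(signal.beta):
        alpha0 = float(logit(cfg.case_fraction))
    else:
        alpha0 = _solve_alpha0(lin, cfg.case_fraction)
    prob = expit(alpha0 + lin)
    y = (rng.random(G.n) < prob).astype(float)
    return PhenotypeVector(values=y, family="binomial")
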