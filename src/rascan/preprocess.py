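"""Quality control and sample splitting ahead of the regional scan.

MAF computation/filtering, windowed greedy LD pruning (PLINK
``--indep-pairwise`` dialect: within each window, while any retained pair has
squared dosage correlation above the threshold, drop the lower-MAF member),
and the random half-splits used for out-of-sample effect estimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genotype_io import GenotypeDataset

__all__ = [
    "SampleSplit",
    "compute_maf",
    "filter_maf",
    "ld_prune",
    "write_prune_lists",
    "split_samples",
]


@dataclass(frozen=True)
class SampleSplit:
    """Disjoint estimation/evaluation index sets covering all samples."""

    estimation_ids: np.ndarray
    evaluation_ids: np.ndarray

    def __post_init__(self) -> None:
        est = np.asarray(self.estimation_ids, dtype=int)
        ev = np.asarray(self.evaluation_ids, dtype=int)
        object.__setattr__(self, "estimation_ids", est)
        object.__setattr__(self, "evaluation_ids", ev)
        if np.intersect1d(est, ev).size:
            raise ValueError("estimation and evaluation sets overlap")


def compute_maf(G: GenotypeDataset) -> np.ndarray:
    """Per-SNP minor allele frequency min(f, 1-f), f = mean dosage / 2.

    Expects imputed dosages (no NaN); values lie in [0, 0.5].
    """
    if G.has_missing():
        raise ValueError("impute missing dosages before computing MAF")
    f = G.dosages.mean(axis=0) / 2.0
    return np.minimum(f, 1.0 - f)


def filter_maf(G: GenotypeDataset, threshold: float = 0.01) -> GenotypeDataset:
    """Keep SNPs with MAF >= threshold (inclusive), preserving order."""
    keep = np.flatnonzero(compute_maf(G) >= threshold)
    if keep.size == 0:
        raise ValueError(
            f"no SNP passes MAF >= {threshold}; review the threshold")
    return G.subset_snps(keep)


def _pairwise_r2(d: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns; constant -> 0."""
    centered = d - d.mean(axis=0)
    sd = centered.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, centered / sd, 0.0)
    r = (z.T @ z) / d.shape[0]
    return r ** 2


def ld_prune(G: GenotypeDataset, r2_threshold: float = 0.2,
             window_snps: int = 50, step_snps: int = 5) -> np.ndarray:
    """Windowed greedy LD pruning; returns kept SNP indices (0-based, sorted).

    Within each window of ``window_snps`` consecutive SNPs (advancing by
    ``step_snps``), while any retained pair has r^2 > ``r2_threshold`` the
    pair with the largest r^2 is resolved by removing its lower-MAF member
    (ties: the later SNP is removed).  Deterministic given input order.
    """
    p = G.p
    maf = compute_maf(G)
    removed = np.zeros(p, dtype=bool)
    start = 0
    while True:
        end = min(start + window_snps, p)
        active = [j for j in range(start, end) if not removed[j]]
        while len(active) > 1:
            r2 = _pairwise_r2(G.dosages[:, active])
            np.fill_diagonal(r2, 0.0)
            i, j = np.unravel_index(np.argmax(r2), r2.shape)
            if r2[i, j] <= r2_threshold:
                break
            a, b = sorted((active[i], active[j]))
            drop = b if maf[b] <= maf[a] else a
            removed[drop] = True
            active.remove(drop)
        if end >= p:
            break
        start += step_snps
    return np.flatnonzero(~removed)


def write_prune_lists(G: GenotypeDataset, kept: np.ndarray,
                      prefix) -> None:
    """Write kept/removed SNP ids as ``prefix.prune.in`` / ``prefix.prune.out``
    (one id per line, PLINK convention)."""
    kept = np.asarray(kept, dtype=int)
    removed = np.setdiff1d(np.arange(G.p), kept)
    from pathlib import Path
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    Path(f"{prefix}.prune.in").write_text(
        "".join(f"{s}\n" for s in G.snp_ids[kept]))
    Path(f"{prefix}.prune.out").write_text(
        "".join(f"{s}\n" for s in G.snp_ids[removed]))


def split_samples(n: int, split_fraction: float = 0.5,
                  seed: int | np.random.SeedSequence = 0) -> SampleSplit:
    """Uniformly random estimation/evaluation partition, reproducible by seed.

    The estimation half has round(split_fraction * n) samples (half up).
    """
    if n < 4:
        raise ValueError("need n >= 4 samples to split")
    n_est = int(math.floor(split_fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return SampleSplit(estimation_ids=np.sort(perm[:n_est]),
                       evaluation_ids=np.sort(perm[n_est:]))
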