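"""Localized polygenic risk scores and the regional association score (RAS).

The method in brief: split the cohort in half; on the estimation half fit the
standard marginal single-SNP GWAS regression y ~ intercept + g_j + X to get
per-SNP effect estimates beta_hat_j; on the evaluation half aggregate the
SNPs inside a window centered on a pivotal SNP into a localized polygenic
risk score

    LPRS_i = sum_{j in window} beta_hat_j * G_ij,

regress the phenotype on the LPRS (adjusting for covariates) and take
AS = -log10(p-value) of the LPRS coefficient as the window's association
strength.  The RAS of a pivotal SNP is the maximum AS over an adaptive
family of windows j +/- t, t in a candidate set T; pivotal SNPs on a regular
index grid turn the per-SNP RAS values into a positional series for peak
detection.  Splitting is repeated several times and the per-repetition RAS
values are averaged to damp the effect-estimation noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .genotype_io import CovariateMatrix, GenotypeDataset, PhenotypeVector
from .preprocess import SampleSplit, split_samples

logger = logging.getLogger("rascan")

__all__ = [
    "ScanConfig",
    "EffectEstimates",
    "RASSeries",
    "estimate_effects",
    "lprs",
    "association_score",
    "ras_at",
    "ras_series",
]

AS_CAP = 300.0  # -log10 p is capped here to avoid underflow infinities
_LN10 = math.log(10.0)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ScanConfig:
    """All tuning knobs of the RAS pipeline.

    ``candidate_T`` is the set of window half-widths (in SNPs) searched at
    each pivotal SNP; ``pivotal_interval`` the index spacing of pivotal SNPs;
    ``n_split_reps`` the number of sample-splitting repetitions averaged.
    The ``cp_*`` fields parameterize the sliding-window change-point stage
    and ``magnitude_threshold`` the final peak filter (None = not yet
    calibrated).
    """

    candidate_T: tuple = tuple(range(5, 105, 5))
    pivotal_interval: int = 10
    n_split_reps: int = 10
    split_fraction: float = 0.5
    cp_window: int = 50
    cp_overlap: float = 0.9
    cp_alpha: float = 0.05
    slope_alpha: float = 0.05
    n_cp_permutations: int = 200
    magnitude_threshold: float | None = None
    seed: int = 0
    in_sample_as: bool = False

    def __post_init__(self) -> None:
        self.candidate_T = tuple(sorted(int(t) for t in self.candidate_T))
        if not self.candidate_T or min(self.candidate_T) < 1:
            raise ValueError("candidate_T must be a nonempty set of positive ints")
        if not 0 < self.cp_overlap < 1:
            raise ValueError("cp_overlap must lie in (0, 1)")
        for name in ("cp_alpha", "slope_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.n_split_reps < 1:
            raise ValueError("n_split_reps must be >= 1")


@dataclass
class EffectEstimates:
    """Per-SNP marginal effect estimates from one split repetition."""

    beta_hat: np.ndarray
    repetition_id: int
    split: SampleSplit


@dataclass
class RASSeries:
    """RAS evaluated on the pivotal-SNP grid of one chromosome.

    ``pivotal_index`` holds 1-based indices into the chromosome's SNP list
    (the external convention used in all exports); helper ``pivotal_idx0``
    gives the 0-based view used for array work.
    """

    pivotal_index: np.ndarray
    position_bp: np.ndarray
    ras: np.ndarray
    t_star: np.ndarray
    snp_id: np.ndarray | None = None
    chromosome: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pivotal_index = np.asarray(self.pivotal_index, dtype=int)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        self.ras = np.asarray(self.ras, dtype=float)
        self.t_star = np.asarray(self.t_star, dtype=int)
        lens = {len(self.pivotal_index), len(self.position_bp),
                len(self.ras), len(self.t_star)}
        if len(lens) != 1:
            raise ValueError("RASSeries arrays must have equal length")
        if np.any(np.diff(self.pivotal_index) <= 0):
            raise ValueError("pivotal_index must be strictly increasing")
        if not np.all(np.isfinite(self.ras)) or np.any(self.ras < 0):
            raise ValueError("ras values must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.ras)

    @property
    def pivotal_idx0(self) -> np.ndarray:
        return self.pivotal_index - 1

    def to_frame(self) -> pd.DataFrame:
        p = len(self)
        return pd.DataFrame({
            "snp_id": self.snp_id if self.snp_id is not None else [""] * p,
            "chromosome": (self.chromosome if self.chromosome is not None
                           else ["1"] * p),
            "position_bp": self.position_bp,
            "pivotal_index": self.pivotal_index,
            "ras": self.ras,
            "t_star": self.t_star,
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "RASSeries":
        df = pd.read_csv(path, sep="\t")
        return cls(pivotal_index=df["pivotal_index"].to_numpy(),
                   position_bp=df["position_bp"].to_numpy(),
                   ras=df["ras"].to_numpy(),
                   t_star=df["t_star"].to_numpy(),
                   snp_id=df["snp_id"].to_numpy(dtype=object),
                   chromosome=df["chromosome"].to_numpy(dtype=object))


# ---------------------------------------------------------------------------
# regression helpers
# ---------------------------------------------------------------------------

def _nuisance_basis(n: int, X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of span{intercept, covariates} (n x (k+1))."""
    design = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    q, _ = np.linalg.qr(design)
    return q

def _residualize(v: np.ndarray, Q: np.ndarray) -> np.ndarray:
    return v - Q @ (Q.T @ v)


def _logistic_newton(Z: np.ndarray, y: np.ndarray, max_iter: int = 50,
                     tol: float = 1e-8):
    """Plain Newton–Raphson logistic ML.  Returns (beta, cov, converged)."""
    n, m = Z.shape
    beta = np.zeros(m)
    cov = None
    for _ in range(max_iter):
        eta = Z @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        H = (Z * w[:, None]).T @ Z
        grad = Z.T @ (y - mu)
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(m), grad)
        except np.linalg.LinAlgError:
            return beta, None, False
        beta = beta + step
        if np.max(np.abs(beta)) > 1e3:  # separation drift
            return beta, None, False
        if np.max(np.abs(step)) < tol:
            try:
                cov = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                return beta, None, False
            return beta, cov, True
    return beta, cov, False


def _as_from_t(t_abs: np.ndarray, df: int) -> np.ndarray:
    """AS = -log10(two-sided p) from |t| with underflow-safe log tails."""
    logp = math.log(2.0) + stats.t.logsf(t_abs, df)
    return np.minimum(-logp / _LN10, AS_CAP)


# ---------------------------------------------------------------------------
# effect estimation (marginal single-SNP GWAS on the estimation half)
# ---------------------------------------------------------------------------

def estimate_effects(G: GenotypeDataset, y: PhenotypeVector,
                     X: CovariateMatrix, family: str | None = None,
                     split: SampleSplit | None = None,
                     repetition_id: int = 0) -> EffectEstimates:
    """Marginal per-SNP effects on the estimation half of ``split``.

    For each SNP j the coefficient of g_j in y ~ intercept + g_j + X is
    estimated on the estimation half only — ordinary least squares for a
    gaussian phenotype (via Frisch–Waugh residualization, vectorized across
    SNPs), Newton maximum-likelihood logistic regression for a binomial one.
    SNPs with zero dosage variance on the estimation half, and logistic fits
    that fail to converge (including perfect separation), get beta_hat = 0.
    """
    family = family or y.family
    if split is None:
        split = SampleSplit(estimation_ids=np.arange(G.n),
                            evaluation_ids=np.empty(0, dtype=int))
    est = split.estimation_ids
    k = X.k
    if len(est) < k + 3:
        raise ValueError("estimation half too small for the design")
    Ge = G.dosages[est]
    ye = y.values[est]
    Xe = X.values[est]

    if family == "gaussian":
        Q = _nuisance_basis(len(est), Xe)
        Gr = _residualize(Ge, Q)
        yr = _residualize(ye, Q)
        denom = np.einsum("ij,ij->j", Gr, Gr)
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = np.where(denom > 1e-10, (Gr.T @ yr) / denom, 0.0)
    elif family == "binomial":
        p = G.p
        beta = np.zeros(p)
        n_fail = 0
        base = np.column_stack([np.ones(len(est)), np.zeros(len(est)), Xe])
        for j in range(p):
            g = Ge[:, j]
            if g.std() < 1e-12:
                continue
            base[:, 1] = g
            b, _, ok = _logistic_newton(base, ye)
            if ok:
                beta[j] = b[1]
            else:
                n_fail += 1
        if n_fail:
            logger.warning(
                "logistic effect estimation failed to converge for %d SNP(s); "
                "their beta_hat was set to 0", n_fail)
    else:
        raise ValueError(f"unknown family {family!r}")
    return EffectEstimates(beta_hat=beta, repetition_id=repetition_id,
                           split=split)


# ---------------------------------------------------------------------------
# LPRS and the association score
# ---------------------------------------------------------------------------

def lprs(G: GenotypeDataset, beta_hat: np.ndarray, index_set: np.ndarray,
         sample_indices: np.ndarray | None = None) -> np.ndarray:
    """Localized PRS: sum_j beta_hat_j * dosage_ij over ``index_set``.

    ``index_set`` holds 0-based SNP column indices; with all p SNPs this is
    the ordinary genome-wide PRS.  ``sample_indices`` restricts the rows
    (default: all samples).
    """
    index_set = np.asarray(index_set, dtype=int)
    if index_set.size == 0:
        raise ValueError("index_set must be nonempty")
    d = G.dosages if sample_indices is None else G.dosages[sample_indices]
    return d[:, index_set] @ np.asarray(beta_hat)[index_set]


def association_score(lprs_values: np.ndarray, y: np.ndarray,
                      X: np.ndarray | CovariateMatrix | None = None,
                      family: str = "gaussian") -> float:
    """AS = -log10 p for the LPRS coefficient in y ~ intercept + LPRS + X.

    Gaussian: closed-form least squares with a two-sided t test on the LPRS
    coefficient (df = n - 2 - k).  Binomial: logistic ML with a two-sided
    Wald test.  The p-value is computed in log space and the score capped at
    300.  A zero-variance LPRS (after covariate projection) carries no
    signal and scores 0 by convention.
    """
    lprs_values = np.asarray(lprs_values, dtype=float)
    y = np.asarray(y, dtype=float)
    if isinstance(X, CovariateMatrix):
        X = X.values
    X = np.empty((len(y), 0)) if X is None else np.asarray(X, dtype=float)
    n, k = len(y), X.shape[1]

    if family == "gaussian":
        Q = _nuisance_basis(n, X)
        lr = _residualize(lprs_values, Q)
        ss_l = float(lr @ lr)
        if ss_l <= 1e-12 * max(1.0, float(lprs_values @ lprs_values)):
            return 0.0
        yr = _residualize(y, Q)
        ss_y = float(yr @ yr)
        if ss_y <= 0:
            return 0.0
        r = float(lr @ yr) / math.sqrt(ss_l * ss_y)
        df = n - 2 - k
        if df < 1:
            raise ValueError("not enough samples for the association test")
        r2 = min(r * r, 1.0)
        if r2 >= 1.0:
            return AS_CAP
        t_abs = abs(r) * math.sqrt(df / (1.0 - r2))
        return float(_as_from_t(np.array(t_abs), df))
    if family == "binomial":
        if np.std(lprs_values) < 1e-12:
            return 0.0
        Z = np.column_stack([np.ones(n), lprs_values, X])
        b, cov, ok = _logistic_newton(Z, y)
        if not ok or cov is None or cov[1, 1] <= 0:
            logger.warning("logistic association fit did not converge; AS = 0")
            return 0.0
        z = abs(b[1]) / math.sqrt(cov[1, 1])
        logp = math.log(2.0) + stats.norm.logsf(z)
        return float(min(-logp / _LN10, AS_CAP))
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# RAS at one pivotal SNP and over the pivotal grid
# ---------------------------------------------------------------------------

def _window_bounds(j: int, t: int, p: int) -> tuple[int, int]:
    """Closed 0-based SNP bounds of the window j +/- t, clipped to [0, p-1]."""
    return max(j - t, 0), min(j + t, p - 1)


def ras_at(j: int, G: GenotypeDataset, beta_hat: np.ndarray,
           y: np.ndarray, X: np.ndarray | CovariateMatrix | None,
           candidate_T, family: str = "gaussian",
           sample_indices: np.ndarray | None = None) -> tuple[float, int]:
    """RAS of pivotal SNP ``j`` (0-based): max AS over windows j +/- t, t in T.

    Ties in the maximum are broken toward the smallest t (most parsimonious
    window).  Returns (ras, t_star).
    """
    candidate_T = sorted(int(t) for t in candidate_T)
    if not candidate_T:
        raise ValueError("candidate_T must be nonempty")
    yv = np.asarray(y, dtype=float)
    if sample_indices is not None:
        yv = yv[sample_indices]
        if isinstance(X, CovariateMatrix):
            X = X.values
        X = X[sample_indices] if X is not None and np.size(X) else X
    best_as, best_t = -np.inf, candidate_T[0]
    for t in candidate_T:
        lo, hi = _window_bounds(j, t, G.p)
        vals = lprs(G, beta_hat, np.arange(lo, hi + 1), sample_indices)
        a = association_score(vals, yv, X, family)
        if a > best_as:
            best_as, best_t = a, t
    return float(best_as), int(best_t)


def _as_matrix_gaussian(dosages: np.ndarray, beta: np.ndarray,
                        y: np.ndarray, X: np.ndarray,
                        pivots0: np.ndarray, Ts: list[int]) -> np.ndarray:
    """AS for every (pivotal SNP, t) window on one sample half, batched.

    Windowed LPRS vectors come from a prefix sum of the beta-weighted dosage
    matrix; covariates are projected out once and the t statistic follows
    from the residual correlation (Frisch–Waugh).  Numerically identical to
    calling :func:`association_score` window by window.
    """
    n, p = dosages.shape
    k = X.shape[1]
    df = n - 2 - k
    if df < 1:
        raise ValueError("not enough samples for the association test")
    C = np.concatenate([np.zeros((n, 1)), np.cumsum(dosages * beta, axis=1)],
                       axis=1)
    lo = np.maximum(pivots0[:, None] - np.asarray(Ts)[None, :], 0)
    hi = np.minimum(pivots0[:, None] + np.asarray(Ts)[None, :], p - 1)
    L = C[:, (hi + 1).ravel()] - C[:, lo.ravel()]  # (n, n_piv*n_T)

    Q = _nuisance_basis(n, X)
    Lr = _residualize(L, Q)
    yr = _residualize(y, Q)
    ss_l = np.einsum("ij,ij->j", Lr, Lr)
    ss_y = float(yr @ yr)
    scale = 1e-12 * np.maximum(1.0, np.einsum("ij,ij->j", L, L))
    ok = (ss_l > scale) & (ss_y > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Lr.T @ yr) / np.sqrt(ss_l * ss_y)
    r = np.clip(np.where(ok, r, 0.0), -1.0, 1.0)
    r2 = r * r
    t_abs = np.where(r2 < 1.0,
                     np.abs(r) * np.sqrt(df / np.maximum(1.0 - r2, 1e-300)),
                     np.inf)
    out = np.where(ok, _as_from_t(t_abs, df), 0.0)
    return out.reshape(len(pivots0), len(Ts))


def ras_series(G: GenotypeDataset, y: PhenotypeVector, X: CovariateMatrix,
               family: str | None = None,
               config: ScanConfig | None = None) -> RASSeries:
    """RAS over the pivotal-SNP grid, averaged over split repetitions.

    Pivotal SNPs sit at 1-based indices 1, 1+d, 1+2d, ... for
    d = ``config.pivotal_interval``.  Each repetition draws a fresh random
    half-split, estimates effects on the estimation half and scores every
    (pivot, t) window on the evaluation half (or the estimation half when
    ``config.in_sample_as``).  The reported ras is the mean over repetitions
    of the per-repetition RAS (max over t); t_star maximizes the
    repetition-averaged per-t AS profile, ties to the smallest t.  Fully
    reproducible under ``config.seed``.
    """
    config = config or ScanConfig()
    family = family or y.family
    p, n = G.p, G.n
    d = config.pivotal_interval
    if p < d:
        raise ValueError("need p >= pivotal_interval")
    pivots0 = np.arange(0, p, d)
    Ts = list(config.candidate_T)
    n_piv = len(pivots0)

    as_sum = np.zeros((n_piv, len(Ts)))
    ras_sum = np.zeros(n_piv)
    root = np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 101])
    for rep, child in enumerate(root.spawn(config.n_split_reps)):
        split = split_samples(n, config.split_fraction, child)
        eff = estimate_effects(G, y, X, family, split, repetition_id=rep)
        half = (split.estimation_ids if config.in_sample_as
                else split.evaluation_ids)
        if family == "gaussian":
            A = _as_matrix_gaussian(G.dosages[half], eff.beta_hat,
                                    y.values[half], X.values[half],
                                    pivots0, Ts)
        else:
            A = np.empty((n_piv, len(Ts)))
            yv = y.values[half]
            Xv = X.values[half]
            for a, j in enumerate(pivots0):
                for b, t in enumerate(Ts):
                    lo, hi = _window_bounds(j, t, p)
                    vals = lprs(G, eff.beta_hat, np.arange(lo, hi + 1), half)
                    A[a, b] = association_score(vals, yv, Xv, family)
        as_sum += A
        ras_sum += A.max(axis=1)

    mean_profile = as_sum / config.n_split_reps
    t_star = np.asarray(Ts)[np.argmax(mean_profile, axis=1)]  # first = smallest t
    return RASSeries(
        pivotal_index=pivots0 + 1,
        position_bp=G.position_bp[pivots0],
        ras=ras_sum / config.n_split_reps,
        t_star=t_star,
        snp_id=G.snp_ids[pivots0],
        chromosome=G.chromosome[pivots0],
    )
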