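"""Genotype, phenotype and covariate I/O.

Reads PLINK 1 binary triplets (.bed/.bim/.fam) and plain dosage tables into
the pipeline's data model.  Dosages are minor-allele counts in {0, 1, 2};
missing genotypes are permitted on input and mean-imputed per SNP before any
analysis.  Genotype-file sample order is canonical: phenotype and covariate
tables are reindexed to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("rascan")

__all__ = [
    "GenotypeDataset",
    "PhenotypeVector",
    "CovariateMatrix",
    "read_plink",
    "write_plink",
    "read_table",
    "write_table",
]


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class GenotypeDataset:
    """n x p dosage matrix of minor-allele counts plus SNP metadata.

    ``dosages`` is float so that NaN can mark missing genotypes on input;
    :meth:`impute_missing` replaces NaN by the per-SNP mean dosage, after
    which every value lies in the closed interval [0, 2].  Positions are
    1-based base pairs and must be strictly increasing within a chromosome.
    """

    dosages: np.ndarray
    sample_ids: np.ndarray
    snp_ids: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray
    allele_minor: np.ndarray = field(default=None)
    allele_major: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        if self.allele_minor is None:
            self.allele_minor = np.asarray(["A"] * self.p, dtype=object)
        if self.allele_major is None:
            self.allele_major = np.asarray(["B"] * self.p, dtype=object)
        self.allele_minor = np.asarray(self.allele_minor, dtype=object)
        self.allele_major = np.asarray(self.allele_major, dtype=object)
        self.validate()

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def p(self) -> int:
        return self.dosages.shape[1]

    def validate(self) -> None:
        n, p = self.dosages.shape
        if n < 1 or p < 1:
            raise ValueError("genotype matrix must have n >= 1 and p >= 1")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        for name in ("snp_ids", "chromosome", "position_bp",
                     "allele_minor", "allele_major"):
            if len(getattr(self, name)) != p:
                raise ValueError(f"{name} length does not match dosage columns")
        for chrom in pd.unique(self.chromosome):
            pos = self.position_bp[self.chromosome == chrom]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and (vals.min() < 0 or vals.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosages).any())

    def impute_missing(self) -> "GenotypeDataset":
        """Replace missing dosages by the per-SNP mean (keeps n constant)."""
        if not self.has_missing():
            return self
        d = self.dosages.copy()
        col_mean = np.nanmean(d, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)  # all-missing SNP
        idx = np.where(np.isnan(d))
        d[idx] = col_mean[idx[1]]
        return replace(self, dosages=d)

    def subset_snps(self, indices: np.ndarray) -> "GenotypeDataset":
        indices = np.asarray(indices, dtype=int)
        return GenotypeDataset(
            dosages=self.dosages[:, indices],
            sample_ids=self.sample_ids,
            snp_ids=self.snp_ids[indices],
            chromosome=self.chromosome[indices],
            position_bp=self.position_bp[indices],
            allele_minor=self.allele_minor[indices],
            allele_major=self.allele_major[indices],
        )

    def subset_samples(self, indices: np.ndarray) -> "GenotypeDataset":
        indices = np.asarray(indices, dtype=int)
        return replace(self, dosages=self.dosages[indices],
                       sample_ids=self.sample_ids[indices])


@dataclass
class PhenotypeVector:
    """Phenotype y with its GLM family ('gaussian' or 'binomial')."""

    values: np.ndarray
    family: str = "gaussian"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "binomial" and not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("binomial phenotype must be coded 0/1")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class CovariateMatrix:
    """n x k covariate matrix (k may be 0); no missing values allowed."""

    values: np.ndarray
    names: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values.reshape(-1, 1)
        if self.values.size == 0:
            self.values = self.values.reshape(len(self.values), 0)
        if np.isnan(self.values).any():
            raise ValueError("covariates must not contain missing values")
        if self.values.shape[1] != len(self.names):
            raise ValueError("covariate names do not match columns")

    @property
    def k(self) -> int:
        return self.values.shape[1]

    @classmethod
    def empty(cls, n: int) -> "CovariateMatrix":
        return cls(values=np.empty((n, 0)), names=[])


# ---------------------------------------------------------------------------
# minor-allele orientation
# ---------------------------------------------------------------------------

def orient_minor(G: GenotypeDataset) -> GenotypeDataset:
    """Flip columns so every dosage counts the minor allele.

    Columns whose counted-allele frequency exceeds 0.5 are replaced by
    ``2 - dosage`` and their allele labels swapped.  Idempotent: frequencies
    after one application are all <= 0.5 (ties at 0.5 are left as read).
    """
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(G.dosages, axis=0) / 2.0
    flip = freq > 0.5
    if not flip.any():
        return G
    d = G.dosages.copy()
    d[:, flip] = 2.0 - d[:, flip]
    a_min = G.allele_minor.copy()
    a_maj = G.allele_major.copy()
    a_min[flip], a_maj[flip] = G.allele_major[flip], G.allele_minor[flip]
    return replace(G, dosages=d, allele_minor=a_min, allele_major=a_maj)


def _chrom_sort_key(labels: np.ndarray) -> np.ndarray:
    """Numeric chromosomes sort numerically, others lexically after them."""
    def key(c):
        s = str(c)
        return (0, int(s), "") if s.isdigit() else (1, 0, s)
    order = sorted(range(len(labels)), key=lambda i: key(labels[i]))
    return np.asarray(order, dtype=int)


# ---------------------------------------------------------------------------
# PLINK 1 binary triplet
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major mode
# 2-bit codes, per SNP, sample-packed little-endian within a byte:
# 00 = hom A1 (2 copies), 01 = missing, 10 = het, 11 = hom A2 (0 copies)
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink(prefix: str | Path) -> GenotypeDataset:
    """Read a PLINK 1 ``prefix.bed/.bim/.fam`` triplet.

    Dosages are oriented as minor-allele counts (columns with counted-allele
    frequency > 0.5 are flipped, labels swapped) and SNPs are sorted by
    (chromosome, position).  Missing genotypes come back as NaN.
    """
    prefix = Path(prefix)
    paths = {ext: prefix.with_suffix(f".{ext}") for ext in ("bed", "bim", "fam")}
    for ext, path in paths.items():
        if not path.exists():
            raise FileNotFoundError(f"PLINK .{ext} file not found: {path}")

    fam = pd.read_csv(paths["fam"], sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype=str)
    bim = pd.read_csv(paths["bim"], sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "snp": str, "a1": str, "a2": str})
    n, p = len(fam), len(bim)

    raw = np.fromfile(paths["bed"], dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(f"{paths['bed']}: not a SNP-major PLINK 1 .bed file")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if body.size != p * bytes_per_snp:
        raise ValueError(
            f"{paths['bed']}: size implies a different sample/SNP count than "
            f".fam ({n}) / .bim ({p})")
    body = body.reshape(p, bytes_per_snp)
    # unpack 2-bit codes, sample i lives in byte i//4 at bit offset 2*(i%4)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(p, -1)[:, :n]
    dosages = _CODE_TO_DOSAGE[codes].T  # (n, p), counts of A1

    # stable sort by (chromosome rank, position) before construction so the
    # strictly-increasing-position invariant can be validated
    chrom = bim["chrom"].to_numpy(dtype=object)
    pos = bim["pos"].to_numpy()
    chrom_order = _chrom_sort_key(chrom)
    chrom_rank = {c: i for i, c in enumerate(pd.unique(chrom[chrom_order]))}
    keys = np.array([chrom_rank[c] for c in chrom])
    order = np.lexsort((pos, keys))

    G = GenotypeDataset(
        dosages=dosages[:, order],
        sample_ids=fam["iid"].to_numpy(dtype=object),
        snp_ids=bim["snp"].to_numpy(dtype=object)[order],
        chromosome=chrom[order],
        position_bp=pos[order],
        allele_minor=bim["a1"].to_numpy(dtype=object)[order],
        allele_major=bim["a2"].to_numpy(dtype=object)[order],
    )
    return orient_minor(G)


def write_plink(G: GenotypeDataset, prefix: str | Path) -> None:
    """Write a GenotypeDataset as a PLINK 1 triplet (A1 = minor allele)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, p = G.n, G.p
    fam = pd.DataFrame({
        "fid": G.sample_ids, "iid": G.sample_ids, "father": 0, "mother": 0,
        "sex": 0, "pheno": -9,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    bim = pd.DataFrame({
        "chrom": G.chromosome, "snp": G.snp_ids, "cm": 0,
        "pos": G.position_bp, "a1": G.allele_minor, "a2": G.allele_major,
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    d = G.dosages
    codes = np.full(d.shape, 1, dtype=np.uint8)  # missing
    codes[d == 2] = 0b00
    codes[d == 1] = 0b10
    codes[d == 0] = 0b11
    pad = (-n) % 4
    if pad:
        codes = np.vstack([codes, np.full((pad, p), 0b11, dtype=np.uint8)])
    codes = codes.T.reshape(p, -1, 4)  # (p, bytes_per_snp, 4)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (codes << shifts[None, None, :]).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# dosage / phenotype / covariate tables
# ---------------------------------------------------------------------------

def read_table(genotype_tsv: str | Path,
               phenotype_tsv: str | Path,
               covariate_tsv: str | Path | None = None,
               ) -> tuple[GenotypeDataset, PhenotypeVector, CovariateMatrix]:
    """Read dosage, phenotype and optional covariate TSVs.

    The genotype table has a header row of SNP ids and a first column of
    sample ids.  Phenotype and covariate tables are keyed by sample id and
    are intersected with and reindexed to the genotype sample order.  The
    phenotype family is binomial iff its values are a subset of {0, 1}.
    Sample ids in the phenotype table without genotypes are dropped with a
    warning.  Positions/chromosomes are read from optional ``#chrom`` /
    ``#pos`` metadata rows if present, else synthesized (chrom "1",
    positions 1..p).
    """
    geno = pd.read_csv(genotype_tsv, sep="\t", index_col=0)
    meta_rows = [r for r in geno.index if str(r).startswith("#")]
    chrom = pos = None
    if meta_rows:
        meta = geno.loc[meta_rows]
        geno = geno.drop(index=meta_rows)
        if "#chrom" in meta.index:
            chrom = _clean_chrom_labels(meta.loc["#chrom"])
        if "#pos" in meta.index:
            pos = meta.loc["#pos"].astype(float).astype(int).to_numpy()
    try:
        dosages = geno.to_numpy(dtype=float)
    except ValueError as exc:
        bad = _first_non_numeric(geno)
        raise ValueError(
            f"non-numeric dosage at sample {bad[0]!r}, SNP {bad[1]!r}") from exc
    p = dosages.shape[1]
    G = GenotypeDataset(
        dosages=dosages,
        sample_ids=geno.index.astype(str).to_numpy(dtype=object),
        snp_ids=geno.columns.astype(str).to_numpy(dtype=object),
        chromosome=chrom if chrom is not None else np.array(["1"] * p, dtype=object),
        position_bp=pos if pos is not None else np.arange(1, p + 1),
    )

    pheno = pd.read_csv(phenotype_tsv, sep="\t", index_col=0)
    pheno.index = pheno.index.astype(str)
    extra = pheno.index.difference(G.sample_ids)
    if len(extra):
        logger.warning("dropping %d phenotype sample(s) without genotypes: %s",
                       len(extra), list(extra[:5]))
    missing = [s for s in G.sample_ids if s not in pheno.index]
    if missing:
        raise ValueError(f"samples missing from phenotype table: {missing[:5]}")
    yvals = pheno.iloc[:, 0].reindex(G.sample_ids).to_numpy(dtype=float)
    family = "binomial" if np.isin(yvals, (0.0, 1.0)).all() else "gaussian"
    y = PhenotypeVector(values=yvals, family=family)

    if covariate_tsv is None:
        X = CovariateMatrix.empty(G.n)
    else:
        cov = pd.read_csv(covariate_tsv, sep="\t", index_col=0)
        cov.index = cov.index.astype(str)
        cov = cov.reindex(G.sample_ids)
        if cov.isna().any().any():
            raise ValueError("covariate table has missing samples or values")
        X = CovariateMatrix(values=cov.to_numpy(dtype=float),
                            names=list(cov.columns))
    return G, y, X


def write_table(G: GenotypeDataset, path: str | Path,
                include_meta: bool = True) -> None:
    """Write the dosage-table TSV (inverse of :func:`read_table`)."""
    df = pd.DataFrame(G.dosages, index=G.sample_ids, columns=G.snp_ids)
    if include_meta:
        meta = pd.DataFrame(
            [G.chromosome, G.position_bp],
            index=["#chrom", "#pos"], columns=G.snp_ids)
        df = pd.concat([meta, df])
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def _clean_chrom_labels(values) -> np.ndarray:
    """Normalize chromosome labels: integral floats from TSV parsing ("1.0")
    become plain integer strings ("1")."""
    out = []
    for v in values:
        try:
            f = float(v)
            out.append(str(int(f)) if f.is_integer() else str(v))
        except (TypeError, ValueError):
            out.append(str(v))
    return np.asarray(out, dtype=object)


def _first_non_numeric(df: pd.DataFrame) -> tuple:
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            return df.index[bad.argmax()], col
    return "?", "?"
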