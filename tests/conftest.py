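import numpy as np
import pytest

from rascan import CovariateMatrix, GenotypeDataset, SimConfig, simulate_genotypes


def make_dataset(columns, positions=None, chrom="1") -> GenotypeDataset:
    """GenotypeDataset from a list of dosage columns (tests' hand fixtures)."""
    d = np.column_stack([np.asarray(c, dtype=float) for c in columns])
    n, p = d.shape
    return GenotypeDataset(
        dosages=d,
        sample_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
        snp_ids=np.array([f"v{j}" for j in range(p)], dtype=object),
        chromosome=np.array([chrom] * p, dtype=object),
        position_bp=(np.asarray(positions, dtype=int) if positions is not None
                     else np.arange(1, p + 1) * 100),
    )


@pytest.fixture(scope="session")
def small_geno() -> GenotypeDataset:
    """300 samples x 80 SNPs with moderate AR(1) LD."""
    return simulate_genotypes(
        SimConfig(n=300, p=80, T_sig=20, ld_rho=0.5, seed=42))


@pytest.fixture(scope="session")
def ld_geno() -> GenotypeDataset:
    """The synthetic-study chromosome: 1000 samples x 500 SNPs, rho = 0.9."""
    return simulate_genotypes(SimConfig(n=1000, p=500, ld_rho=0.9, seed=11))


@pytest.fixture()
def no_covariates():
    def make(n):
        return CovariateMatrix.empty(n)
    return make
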