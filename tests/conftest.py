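import numpy as np
import pandas as pd
import pytest

from mzvqtl import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort():
    """Multi-locus twin cohort reused by read-only pipeline tests."""
    return simulate.simulate_cohort_genome(
        n_pairs=150, n_snps=40, n_cpgs=16, ld_block_size=2, seed=5)


@pytest.fixture
def six_pair_cohort():
    """Tiny hand-checkable cohort: 6 pairs, 1 SNP, 1 CpG."""
    rng = np.random.default_rng(3)
    cov = simulate.simulate_covariates(6, rng)
    g = np.array([0, 1, 2, 1, 0, 1], dtype=float)
    y = rng.uniform(0.2, 0.8, 12)
    return simulate.TwinPairCohort(
        covariates=cov,
        genotypes=pd.DataFrame([g], index=["snp0"],
                               columns=[f"p{i}" for i in range(6)]),
        methylation=pd.DataFrame([y], index=["cg0"],
                                 columns=[f"p{i}_t{t}" for i in range(6)
                                          for t in (1, 2)]),
        snp_pos=pd.DataFrame({"snp": ["snp0"], "chrom": ["1"], "pos": [1000]}),
        cpg_pos=pd.DataFrame({"cpg": ["cg0"], "chrom": ["1"], "pos": [2000]}),
    )
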