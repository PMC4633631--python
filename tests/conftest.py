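import numpy as np
import pytest

from coherit.synthdata import SimParams, simulate_genotypes, simulate_liability_pair


@pytest.fixture(scope="session")
def small_params():
    return SimParams(n_individuals=300, n_snps=120, maf_range=(0.1, 0.5),
                     n_causal=40, h2_trait1=0.5, h2_trait2=0.4, rg_true=0.5,
                     prevalence1=0.2, prevalence2=0.2, mhc_block=(10, 30),
                     mhc_variance_share=0.3, n_snps_x=20, seed=7)


@pytest.fixture(scope="session")
def small_geno(small_params):
    return simulate_genotypes(small_params)


@pytest.fixture(scope="session")
def small_traits(small_params, small_geno):
    effects, y1, y2 = simulate_liability_pair(small_geno, small_params)
    return effects, y1, y2


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
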