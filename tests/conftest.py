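import numpy as np
import pandas as pd
import pytest

from bpfrail.synthdata import (
    LdBlock,
    SimulationConfig,
    simulate_cohort,
    simulate_genotypes,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A small two-block cohort configuration shared across tests."""
    blocks = [
        LdBlock(n_snps=5, maf_range=(0.2, 0.4), rho=0.5, chrom="1", start=1_000_000),
        LdBlock(n_snps=5, maf_range=(0.1, 0.4), rho=0.0, chrom="2", start=5_000_000),
    ]
    rng = np.random.default_rng(7)
    eff = rng.uniform(0.5, 1.2, size=10) * rng.choice([-1.0, 1.0], size=10)
    return SimulationConfig(
        n_individuals=4000,
        ld_blocks=blocks,
        snp_effects_sbp=eff,
        snp_effects_dbp=0.5 * eff,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_genotypes(small_config):
    return simulate_genotypes(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_genotypes):
    return simulate_cohort(small_genotypes, small_config)


@pytest.fixture()
def deficit_frame() -> pd.DataFrame:
    """Hand-constructed 3-person x 49-item deficit table."""
    cols = [f"item{j + 1:02d}" for j in range(49)]
    data = np.zeros((3, 49))
    data[1, :] = 1.0
    data[2, :6] = 1.0
    return pd.DataFrame(data, index=["a", "b", "c"], columns=cols)
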