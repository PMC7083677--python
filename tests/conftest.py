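import numpy as np
import pytest

from herbivar import (
    ChainConfig,
    DesignSpec,
    GroupKey,
    TrueParams,
    fit_bivariate_animal_model,
    partition_groups,
    simulate_dataset,
)

#: true latent genetic covariance used by the recovery fixtures
TRUE_G = np.array([[0.3, -0.15], [-0.15, 0.3]])


@pytest.fixture(scope="session")
def table1_design() -> DesignSpec:
    """The study layout: 2 US + 3 JP populations x 10 genotypes, 5 gardens, 5 ramets."""
    return DesignSpec()


@pytest.fixture(scope="session")
def default_params() -> TrueParams:
    return TrueParams()


@pytest.fixture(scope="session")
def dataset(table1_design, default_params):
    return simulate_dataset(table1_design, default_params, seed=11)


@pytest.fixture(scope="session")
def jp_jp_subset(dataset, table1_design, default_params):
    """The 30-genotype x 15-replicate group, regenerated with its own seed."""
    df = simulate_dataset(table1_design, default_params, seed=100)
    return partition_groups(df)[GroupKey("JP", "JP")]


@pytest.fixture(scope="session")
def jp_jp_fit(jp_jp_subset):
    """A reduced-schedule fit of the bivariate animal model (1,000 draws)."""
    chain = ChainConfig(n_iter=6_000, burn_in=2_000, thin=4, seed=500)
    return fit_bivariate_animal_model(jp_jp_subset, chain=chain)


@pytest.fixture(scope="session")
def small_subset(table1_design, default_params):
    """A small US-origin group for quick structural fits."""
    df = simulate_dataset(table1_design, default_params, seed=42)
    return partition_groups(df)[GroupKey("US", "US")]
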