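import numpy as np
import pytest

from indirectgwas import (
    CovariateMatrix,
    SimulationConfig,
    simulate_genotypes,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared across tests: genotypes, quantitative
    phenotypes, covariates and the config that produced them."""
    cfg = SimulationConfig(
        n_individuals=300, n_variants=60, n_phenotypes=6, n_covariates=3, seed=42
    )
    G = simulate_genotypes(cfg)
    X, Z, truth = simulate_phenotypes(G, cfg)
    return cfg, G, X, Z, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def intercept_only():
    def make(n: int) -> CovariateMatrix:
        return CovariateMatrix.with_intercept(n=n)

    return make
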