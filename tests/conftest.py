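import numpy as np
import pandas as pd
import pytest

import crossprs as cp


@pytest.fixture(scope="session")
def small_pop_model():
    return cp.PopulationModel(n_blocks=12, snps_per_block=8, fst=0.1,
                              within_block_rho=0.9,
                              ancestral_freq_range=(0.15, 0.85))


@pytest.fixture(scope="session")
def small_panel(small_pop_model):
    return cp.generate_haplotype_panel(small_pop_model, "POP1", 400, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_panel):
    dm = cp.DiseaseModel(causal_fraction=0.25, h2_liability=0.4,
                         prevalence_K=0.1)
    return cp.generate_phenotypes(small_panel, dm, seed=7)


@pytest.fixture(scope="session")
def small_sumstats(small_cohort):
    return cp.generate_discovery_sumstats(small_cohort, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_covariates(n, rng):
    """Covariate table with the layout the evaluation stage expects."""
    return pd.DataFrame({
        "age": rng.normal(41, 14, n),
        "sex": rng.integers(0, 2, n),
        **{f"pc{i}": rng.normal(0, 1, n) for i in range(1, 5)},
    })
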