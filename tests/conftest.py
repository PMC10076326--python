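import numpy as np
import pandas as pd
import pytest

from gutlink.synthetic import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort, shared read-only across tests."""
    return simulate_cohort(seed=1)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Fully deterministic cohort: no BW noise, no expression noise."""
    return simulate_cohort(
        CohortConfig(seed=3, noise_sd_bw=0.0, noise_cv_expr=0.0)
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort for fast IO/CLI round-trips."""
    return simulate_cohort(
        CohortConfig(seed=5, n_genes=40, n_taxa=40, n_planted_taxa=4,
                     planted_family_size=3, n_planted_genes=4)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def toy_distance(values, labels) -> pd.DataFrame:
    return pd.DataFrame(values, index=list(labels), columns=list(labels), dtype=float)
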