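import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from guildomics.simulate import CohortConfig, simulate_cohort

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic study (seed 42), shared across tests."""
    return simulate_cohort(CohortConfig())


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast end-to-end style tests."""
    cfg = CohortConfig(
        n_patients=24, n_severe=10, n_controls=20, n_otus=80, n_guilds=8,
        n_fecal_mets=60, n_serum_mets=60, n_modules=4, n_coupled_modules=3,
        n_disease_modules=2, n_serum_patients=16, n_serum_controls=14,
        n_prognostic_otus=3, seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_count_table(matrix, samples=None, otus=None, **kwargs):
    from guildomics.containers import CountTable

    matrix = np.asarray(matrix)
    samples = samples or [f"s{i}" for i in range(matrix.shape[0])]
    otus = otus or [f"o{j}" for j in range(matrix.shape[1])]
    return CountTable(pd.DataFrame(matrix, index=samples, columns=otus), **kwargs)
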