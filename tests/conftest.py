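import dataclasses

import numpy as np
import pytest

from tacpk2pd import np_fit
from tacpk2pd.synthetic_data import default_population, generate_cohort


@pytest.fixture(scope="session")
def default_config():
    return default_population()


@pytest.fixture(scope="session")
def cohort32(default_config):
    """The standard study-sized synthetic cohort (n = 32)."""
    return generate_cohort(default_config, seed=1)


@pytest.fixture(scope="session")
def fitted_model(cohort32):
    """Nonparametric population fit of the n = 32 cohort (shared: the fit
    is deterministic given the seed and moderately expensive)."""
    return np_fit.npem_fit(cohort32, seed=0)


@pytest.fixture(scope="session")
def fit_diagnostics(fitted_model, cohort32):
    return np_fit.gof_diagnostics(fitted_model, cohort32)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def config_n(default_config):
    def make(n, **overrides):
        return dataclasses.replace(default_config, n_subjects=n, **overrides)

    return make
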