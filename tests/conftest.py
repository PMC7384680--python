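"""Shared fixtures: the synthetic study and small ensembles are expensive to
build, so they are session-scoped and reused read-only across test modules."""

import numpy as np
import pytest

from gblnet import default_priors, make_study, sample_ensemble
from gblnet.synth import default_true_growth, default_true_parameters


@pytest.fixture(scope="session")
def true_params():
    return default_true_parameters()


@pytest.fixture(scope="session")
def true_growth():
    return default_true_growth()


@pytest.fixture(scope="session")
def study():
    """Synthetic study at the reference conditions (scenario C, 10% noise)."""
    return make_study(seed=3, noise_sd=0.1)


@pytest.fixture(scope="session")
def noiseless_study():
    return make_study(seed=3, noise_sd=0.0, growth_noise_sd=0.0)


@pytest.fixture(scope="session")
def priors():
    return default_priors()


@pytest.fixture(scope="session")
def small_ensemble(priors):
    return sample_ensemble(priors, 50, seed=11)


def random_parameter_sets(n, seed):
    """Random draws from the default priors as ParameterSet objects."""
    ens = sample_ensemble(default_priors(), n, seed=seed)
    return [ens.member(i) for i in range(n)]


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
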