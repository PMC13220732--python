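import numpy as np
import pytest
from hypothesis import settings

from volprior import synthetic_data as sd

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_population():
    spec = sd.PopulationSpec(n_participants=6)
    return spec, sd.sample_population(spec, seed=101)


@pytest.fixture(scope="session")
def small_study(small_population):
    """Six-participant study, both tasks, fixed seed (shared across tests)."""
    spec, pop = small_population
    trials = sd.simulate_study(pop, seed=202, spec=spec)
    return spec, pop, trials


@pytest.fixture(scope="session")
def predictive_fits(small_study):
    from volprior.fitting import RW_SOFTMAX, STATIC_SOFTMAX, fit_dataset

    _, _, trials = small_study
    pred = trials[trials["task"] == "predictive"]
    return fit_dataset(pred, [RW_SOFTMAX, STATIC_SOFTMAX], seed=7, n_starts=4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
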