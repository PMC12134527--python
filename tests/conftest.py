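import warnings

import numpy as np
import pytest

from seamsel import MCMCConfig, TrialDesign, dichotomize, make_scenario_fixture, simulate_cohort


@pytest.fixture(scope="session")
def design():
    return TrialDesign()


@pytest.fixture(scope="session")
def scenario1():
    return make_scenario_fixture(1)


@pytest.fixture(scope="session")
def scenario3():
    return make_scenario_fixture(3)


@pytest.fixture(scope="session")
def fast_mcmc():
    """Reduced sampler settings for unit tests that only need rough posteriors."""
    return MCMCConfig(chains=2, draws=250, warmup=250, min_steps=500)


@pytest.fixture(scope="session")
def null_binary_cohort(design, scenario1):
    """One dichotomized phase-II cohort under the global null."""
    cohort = simulate_cohort(scenario1, design, "phase2", seed=3)
    return dichotomize(cohort, design.t_star)


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    """Reduced-length sampler runs may trip the Rhat warning; tests assert on
    the returned diagnostics instead of the warning channel."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="posterior sampling", category=RuntimeWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
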