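import warnings

import pytest
from hypothesis import HealthCheck, settings

from reacheffort import (
    PopulationParams,
    REDUCED_MCMC,
    draw_population,
    experiment2_design,
    fit_hierarchical,
    run_experiment,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def exp2_cohort():
    return draw_population(PopulationParams(), 8, seed=101)


@pytest.fixture(scope="session")
def exp2_trials(exp2_cohort):
    return run_experiment(exp2_cohort, experiment2_design(),
                          model="log_difference", seed=102)


@pytest.fixture(scope="session")
def logdiff_fit(exp2_trials):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_hierarchical(exp2_trials, "log_difference", cfg=REDUCED_MCMC)
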