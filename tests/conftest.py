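import numpy as np
import pytest

from avoidprior import build_block_design, simulate_subject
from avoidprior.simulate import default_group_params


@pytest.fixture(scope="session")
def robber_design():
    return build_block_design("robber", seed=101)


@pytest.fixture(scope="session")
def factory_design():
    return build_block_design("factory", seed=202)


@pytest.fixture(scope="session")
def two_task_designs(robber_design, factory_design):
    return [robber_design, factory_design]


@pytest.fixture(scope="session")
def bayes_theta():
    """A representative unconstrained parameter vector for the Bayesian learner."""
    mean, _ = default_group_params("bayes")
    return mean + np.array([0.2, 0.4, -0.3])


@pytest.fixture(scope="session")
def bayes_subject(two_task_designs, bayes_theta):
    """One simulated Bayesian-learner subject over a 120-trial session."""
    return simulate_subject("bayes", bayes_theta, two_task_designs, seed=9)
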