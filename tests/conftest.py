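import numpy as np
import pytest

from transtep import agents, fitting


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_twostep_log():
    """20 ISTL agents x 120 two-step trials from moderate group priors."""
    rng = np.random.default_rng(42)
    theta = fitting.moderate_prior(agents.ISTL).sample(20, rng)
    return agents.ISTL.simulate(theta, 120, rng), theta


@pytest.fixture(scope="session")
def small_multigoal_log():
    rng = np.random.default_rng(43)
    theta = fitting.moderate_prior(agents.MULTIGOAL).sample(12, rng)
    return agents.MULTIGOAL.simulate(theta, 90, rng), theta
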