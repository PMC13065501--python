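import numpy as np
import pytest

import misclassem as me


@pytest.fixture(scope="session")
def s1_cohort():
    """A moderate Scenario-1 cohort shared across read-only tests."""
    return me.generate_scenario(me.scenario_config("S1", n=800, seed=42))


@pytest.fixture(scope="session")
def s1_spec():
    return me.ModelSpec()


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
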