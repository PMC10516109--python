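import numpy as np
import pytest

from bindgeom import synthetic_data as sd
from bindgeom.theory import CodeParams


@pytest.fixture(scope="session")
def default_params() -> CodeParams:
    return CodeParams(dLV=1.0, dLA=0.8, dN=0.8, sigma=0.5)


@pytest.fixture(scope="session")
def discrete_session(default_params):
    """Mid-size 4-condition session shared by the pipeline tests."""
    return sd.generate_discrete_session(
        60, default_params, n_trials_per_condition=150, seed=7
    )


@pytest.fixture(scope="session")
def task_session():
    """Full task-driven session with both conjunctive codes present."""
    gen = sd.GenerativeSession(
        task=sd.TaskConfig(n_trials=1500, seed=11), n_neurons=40, seed=11
    )
    return sd.generate_population_session(gen)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
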