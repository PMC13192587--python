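import numpy as np
import pytest

from causalrnn.dag import CausalDag, NoisyOrParams
from causalrnn.task import TaskConfig
from causalrnn.model import RnnParams, TrainConfig, train


@pytest.fixture(scope="session")
def noisy_or() -> NoisyOrParams:
    """Explicit parameters for hand-computed closed forms in unit tests."""
    return NoisyOrParams(p_spont=0.1, p_cause=0.8)


@pytest.fixture(scope="session")
def task3() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def small_task() -> TaskConfig:
    """Short trials for fast simulation-based unit tests."""
    return TaskConfig(n_obs=5, steps_per_obs=2, settle_steps=4)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def random_params() -> RnnParams:
    """A small untrained network for exercising simulation/analysis code paths."""
    r = np.random.default_rng(7)
    j, m = 16, 9
    return RnnParams(
        W=r.normal(0, 1 / np.sqrt(j), (j, j)),
        B=r.normal(0, 0.2, (j, m)),
        C=r.normal(0, 0.3, j),
        tau=5.0,
        dt=1.0,
    )


@pytest.fixture(scope="session")
def trained():
    """One RNN trained to criterion on the 3-node task, shared across tests.

    Training runs once per session with a fixed seed; the behavioral and
    dynamical signature tests all interrogate this model.
    """
    task = TaskConfig()
    cfg = TrainConfig(seed=12)
    params, history = train(task, cfg)
    return params, task, history
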