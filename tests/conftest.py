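import numpy as np
import pandas as pd
import pytest

from rlcross.agent import AgentParams, simulate_session
from rlcross.cohort import CohortSpec, generate_study
from rlcross.task import TaskConfig, make_schedule


@pytest.fixture(scope="session")
def task_config():
    return TaskConfig()


@pytest.fixture(scope="session")
def small_config():
    return TaskConfig(trials_per_pair=10)


@pytest.fixture(scope="session")
def tiny_spec():
    return CohortSpec(n_subjects=4, n_scanned=2, task=TaskConfig(trials_per_pair=10))


@pytest.fixture(scope="session")
def tiny_study(tiny_spec):
    return generate_study(tiny_spec, seed=123)


@pytest.fixture(scope="session")
def default_study():
    """One default-size cohort (behaviour only), shared across tests."""
    return generate_study(CohortSpec(), seed=7, include_roi=False)


def simulate_cell(alpha, beta, r, seed, trials_per_pair=30, n_runs=3, p_high=0.8,
                  condition="gain"):
    """One subject x condition cell simulated under known parameters."""
    cfg = TaskConfig(n_runs=n_runs, trials_per_pair=trials_per_pair, p_high=p_high,
                     conditions=(condition,))
    schedule = make_schedule(cfg, seed)
    rng = np.random.default_rng(seed + 1)
    log = simulate_session({condition: AgentParams(alpha, beta, r)}, schedule, rng)
    return log.rename(columns={"q_chosen": "q_true", "delta": "delta_true"})
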