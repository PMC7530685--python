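import numpy as np
import pytest

from markovcea import (
    CohortTrace,
    MarkovModel,
    StateSpace,
    TransitionMatrix,
    run_study,
)


@pytest.fixture(scope="session")
def two_state_space():
    return StateSpace(("A", "death"), absorbing=frozenset({"death"}))


@pytest.fixture(scope="session")
def coin_model(two_state_space):
    """A -> death with probability 0.5 per cycle."""
    P = np.array([[0.5, 0.5], [0.0, 1.0]])
    return MarkovModel(two_state_space, TransitionMatrix(two_state_space, P), horizon=3)


@pytest.fixture(scope="session")
def default_study():
    """The packaged two-scenario comparison, shared across tests (read-only)."""
    return run_study()


def constant_trace(space: StateSpace, persons: float, horizon: int, state: str) -> CohortTrace:
    """Everyone parked in one state for the whole horizon."""
    occ = np.zeros((horizon + 1, len(space)))
    occ[:, space.index(state)] = persons
    return CohortTrace(space, occ, initial_size=persons)
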