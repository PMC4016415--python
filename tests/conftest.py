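import numpy as np
import pandas as pd
import pytest

from lifecourse.cohort import InitialMix, cohort_result
from lifecourse.estimation import TransitionMatrixSet
from lifecourse.montecarlo import simulate_collection
from lifecourse.panel import PersonYearPanel
from lifecourse.states import DEFAULT_SCHEME, N_STATES, N_TRANSIENT
from lifecourse.synthetic import SynthConfig, generate_panel, make_ground_truth


@pytest.fixture(scope="session")
def truth():
    """Default synthetic ground truth (matrices, mix, cost model)."""
    return make_ground_truth(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def cost_table(truth):
    return truth.cost_model.to_cost_table()


@pytest.fixture(scope="session")
def cohort_res(truth, cost_table):
    return cohort_result(truth.matrices, truth.initial_mix, costs=cost_table, size=100_000)


@pytest.fixture(scope="session")
def small_panel(truth):
    cfg = SynthConfig(n_individuals=3_000, seed=7)
    return generate_panel(truth, cfg)


@pytest.fixture(scope="session")
def small_collection(truth, cost_table):
    return simulate_collection(
        truth.matrices, truth.initial_mix, 2_000, cost_table, seed=11
    )


def make_uniform_matrices(P: np.ndarray) -> TransitionMatrixSet:
    """One 7x7 matrix replicated over all 20 (gender, band) strata."""
    probs = np.broadcast_to(
        P, (2, DEFAULT_SCHEME.n_groups, N_STATES, N_STATES)
    ).copy()
    return TransitionMatrixSet(probs=probs, scheme=DEFAULT_SCHEME)


def single_state_matrices(q: float) -> TransitionMatrixSet:
    """All mass in E1 with constant death probability q; other states die at once."""
    P = np.zeros((N_STATES, N_STATES))
    P[0, 0] = 1.0 - q
    P[0, 6] = q
    P[1:6, 6] = 1.0
    P[6, 6] = 1.0
    return make_uniform_matrices(P)


def e1_mix() -> InitialMix:
    """Half of each gender, everyone healthy at birth."""
    shares = np.zeros((2, N_TRANSIENT))
    shares[:, 0] = 0.5
    return InitialMix(shares=shares)


def panel_from_rows(rows, columns=("person_id", "year", "gender", "age", "state")):
    return PersonYearPanel(pd.DataFrame(list(rows), columns=list(columns)))
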