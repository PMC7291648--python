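import numpy as np
import pandas as pd
import pytest

from msfrail import (
    SimulationScenario,
    TransitionScenario,
    WeibullBaseline,
    build_transition_datasets,
    default_scenario,
    simulate_cohort,
)


def toy_episode_table() -> pd.DataFrame:
    """Two patients, one provider: one in-hospital death, one censored after discharge."""
    return pd.DataFrame(
        {
            "patient_id": [1, 2],
            "provider_id": ["A", "A"],
            "admission_index": [1, 1],
            "admission_day": [0.0, 0.0],
            "discharge_day": [np.nan, 10.0],
            "in_hospital_death": [1, 0],
            "death_day": [5.0, np.nan],
            "followup_end_day": [1826.0, 1826.0],
            "age": [80.0, 70.0],
            "sex": [1, 0],
            "comorb3": [1, 0],
            "n_procedures": [0, 2],
        }
    )


@pytest.fixture
def toy_episodes() -> pd.DataFrame:
    return toy_episode_table()


def flat_scenario(J=20, sizes=(20, 30), rates=(0.07, 0.009, 0.003, 0.002),
                  K=(1, 1, 1, 1), pi=None, w=None, beta=None,
                  max_admissions=5) -> SimulationScenario:
    """Exponential scenario with explicit per-transition rates and beta = 0.

    Convenient for analytic checks: with beta = 0 and K = 1 each transition is
    exponential with the stated rate.
    """
    transitions = {}
    for l in (1, 2, 3, 4):
        k = K[l - 1]
        transitions[l] = TransitionScenario(
            K=k,
            pi=pi[l - 1] if pi else np.full(k, 1.0 / k),
            w=w[l - 1] if w else np.ones(k),
            beta=beta[l - 1] if beta is not None else np.zeros(4),
            baseline=WeibullBaseline(shape=1.0, scale=1.0 / rates[l - 1]),
        )
    return SimulationScenario(
        J=J, provider_size_range=sizes, transitions=transitions,
        max_admissions=max_admissions,
    )


def small_transition_dataset(seed, J=15, sizes=(10, 20), K=2, ratio=3.0,
                             transition=1):
    """A small discharge-transition dataset with known provider labels."""
    w = np.array([1.0, ratio]) if K == 2 else np.ones(1)
    scen = flat_scenario(
        J=J, sizes=sizes,
        K=(K, 1, 1, 1),
        pi=[np.full(K, 1.0 / K), [1.0], [1.0], [1.0]],
        w=[w, [1.0], [1.0], [1.0]],
        beta=[np.array([0.01, 0.2, -0.3, 0.1])] + [np.zeros(4)] * 3,
    )
    cohort = simulate_cohort(scen, seed=seed)
    ds = build_transition_datasets(cohort.episodes)[transition]
    return ds, cohort


@pytest.fixture(scope="session")
def small_cohort():
    scen = default_scenario(J=30, provider_size_range=(20, 50))
    return simulate_cohort(scen, seed=123)
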