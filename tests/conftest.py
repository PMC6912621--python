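import numpy as np
import pytest

from drinkstates import SimConfig, simulate_cohort
from drinkstates.config import LatentClassSpec
from drinkstates.hmm import HmmParameters
from drinkstates.simulate import sample_ztp


def random_params(rng: np.random.Generator, k: int) -> HmmParameters:
    """A random valid hurdle-HMM parameter set for oracle comparisons."""
    return HmmParameters(rng.dirichlet(np.ones(k)),
                         rng.dirichlet(np.ones(k), size=k),
                         rng.uniform(0.1, 0.9, size=k),
                         rng.uniform(0.5, 5.0, size=k))


def simulate_hmm_sequences(params: HmmParameters, n: int, t: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Draw sequences directly from an HMM (independent of the fitter)."""
    out = np.zeros((n, t))
    for i in range(n):
        s = rng.choice(params.k_states, p=params.initial)
        for j in range(t):
            if rng.random() < params.p[s]:
                out[i, j] = sample_ztp(params.lam[s], 1, rng)[0]
            s = rng.choice(params.k_states, p=params.transition[s])
    return out


def three_class_config(n_students: int, seed: int) -> SimConfig:
    """Well-separated three-class cohort with no weekday structure.

    Students never switch class and every arm slope is zero, so each
    student's 28 days are iid draws from their class's hurdle emission:
    exactly a 3-state HMM with a near-identity transition matrix.
    """
    classes = [
        LatentClassSpec("light", 0.4, (0.05,) * 7, 1.2, state_persistence=1.0),
        LatentClassSpec("moderate", 0.35, (0.45,) * 7, 2.5,
                        state_persistence=1.0),
        LatentClassSpec("heavy", 0.25, (0.9,) * 7, 6.0, state_persistence=1.0,
                        frequent_heavy=True),
    ]
    return SimConfig(n_students=n_students, class_spec=classes,
                     arm_slope_logodds={"control": 0.0, "promillekoll": 0.0,
                                        "partyplanner": 0.0},
                     response_rate_by_wave=(1.0, 1.0, 1.0), seed=seed)


@pytest.fixture(scope="session")
def default_cohort():
    """One paper-scale default cohort shared across tests."""
    return simulate_cohort(SimConfig(n_students=1000, seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SimConfig(n_students=120, seed=3))
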