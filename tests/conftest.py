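import numpy as np
import pandas as pd
import pytest

from coevnet.panel import (
    ActorCovariateTable,
    BehaviorVector,
    CoevolutionPanel,
    DirectedNetwork,
)


def make_covariates(n: int, n_periods: int = 2, seed: int = 0) -> ActorCovariateTable:
    """Small deterministic covariate table for unit tests."""
    rng = np.random.default_rng(seed)
    table = pd.DataFrame(
        {
            "female": rng.integers(0, 2, n),
            "grade": rng.integers(9, 13, n),
            "depressive_symptoms": rng.normal(0, 0.5, n),
            "parental_support": rng.normal(0, 0.3, n),
            "parental_monitoring": rng.normal(0, 0.1, n),
            "home_smoking_environment": rng.uniform(0, 3, n),
            "parental_discussion": rng.integers(0, 2, n),
            "mother_education": rng.integers(1, 5, n),
        }
    )
    limnom = rng.choice([-1, 0, 1], size=(n, n_periods), p=[0.05, 0.9, 0.05])
    return ActorCovariateTable(table=table, limited_nomination_change=limnom)


def adjacency_from_edges(n: int, edges) -> np.ndarray:
    x = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        x[i, j] = 1
    return x


@pytest.fixture
def toy_panel() -> CoevolutionPanel:
    """5-actor, 3-wave panel with hand-countable structure."""
    n = 5
    nets = [
        DirectedNetwork(adjacency_from_edges(n, [(0, 1), (1, 0), (2, 3)]), "wave 1"),
        DirectedNetwork(
            adjacency_from_edges(n, [(0, 1), (1, 0), (1, 2), (0, 2)]), "wave 2"
        ),
        DirectedNetwork(adjacency_from_edges(n, [(0, 1), (3, 4)]), "wave 3"),
    ]
    behs = [
        BehaviorVector(np.array([0, 1, 2, 3, 0]), "wave 1"),
        BehaviorVector(np.array([0, 2, 2, 3, 0]), "wave 2"),
        BehaviorVector(np.array([1, 2, 3, 3, 0]), "wave 3"),
    ]
    return CoevolutionPanel(networks=nets, behaviors=behs, covariates=make_covariates(n))
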