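import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from coopsim import Dataset, GameStructure, default_ground_truth, fit_full_model, generate
from dataclasses import replace

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ground_truth():
    return default_ground_truth()


@pytest.fixture(scope="session")
def synth_ds(ground_truth):
    """Default-scale synthetic dataset (30 structures x 50 pairs)."""
    return generate(ground_truth)


@pytest.fixture(scope="session")
def fitted_model(synth_ds):
    return fit_full_model(synth_ds)


@pytest.fixture(scope="session")
def small_ds(ground_truth):
    """Smaller synthetic dataset for the slower cross-validation paths.

    Needs more structures than the 11 structure-level dynamic features, or
    the design matrix is genuinely rank-deficient.
    """
    return generate(replace(ground_truth, n_structures=24, pairs_per_structure=20, seed=11))


@pytest.fixture()
def toy_structure():
    return GameStructure(
        id="toy", r1=0.4, r2=0.6, delta=0.9, error=0.0,
        infinite=0, continuous=0, risk=0, payoffs=(3.0, 0.0, 5.0, 1.0),
    )


@pytest.fixture()
def toy_dataset(toy_structure):
    """Two players, one interaction, three periods: (C,C), (C,D), (D,D)."""
    actions = pd.DataFrame(
        {
            "structure_id": ["toy"] * 6,
            "interaction_id": ["i1"] * 6,
            "player_id": ["a", "b"] * 3,
            "period": [1, 1, 2, 2, 3, 3],
            "action": [1, 1, 1, 0, 0, 0],
        }
    )
    return Dataset.from_actions([toy_structure], actions)
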