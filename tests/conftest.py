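import numpy as np
import pandas as pd
import pytest

from latentprs.simulate import TrueModel, simulate_factors, simulate_item_responses


@pytest.fixture(scope="session")
def true_model() -> TrueModel:
    """Default 51-item bifactor truth used across measurement tests."""
    return TrueModel(seed=5)


@pytest.fixture(scope="session")
def bifactor_sample(true_model):
    """One seeded cohort of n=3000 item responses from the bifactor truth."""
    eta = simulate_factors(None, np.zeros((5, 1)), n=3000, seed=11)
    items = simulate_item_responses(eta, true_model, seed=12)
    return eta, items


@pytest.fixture(scope="session")
def small_model() -> TrueModel:
    """Compact battery (3 blocks would break the layout, so shrink counts)."""
    return TrueModel(
        n_items_per_block=(3, 3, 3, 3),
        categories_per_block=(3, 3, 3, 3),
        seed=9,
    )


def coarsen(latent: np.ndarray, thresholds) -> np.ndarray:
    """Cut a continuous latent column into ordinal categories."""
    return np.searchsorted(np.asarray(thresholds), latent)
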