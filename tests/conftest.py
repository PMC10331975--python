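import numpy as np
import pytest

import raschclimate as rc
from raschclimate.rsm import EstimationSettings

TEN_ITEMS = tuple(f"I{i}" for i in range(1, 11))


@pytest.fixture(scope="session")
def model_true_cohort():
    """N=1000 cohort drawn exactly from the rating-scale model, with truth."""
    cfg = rc.SimulationConfig(
        n_persons=1000,
        items=TEN_ITEMS,
        n_categories=5,
        theta_sd=1.5,
        delta_range=(-1.5, 1.5),
        seed=42,
    )
    m, factors, truth = rc.simulate_responses(cfg)
    return m, factors, truth


@pytest.fixture(scope="session")
def fitted_cohort(model_true_cohort):
    m, factors, truth = model_true_cohort
    params = rc.fit_jmle(m)
    return m, factors, truth, params


@pytest.fixture(scope="session")
def hse_cohort():
    """Survey-shaped default cohort (761 persons, 11 items) with its fit."""
    m, factors, truth = rc.simulate_responses(rc.hse_default_config(seed=7))
    params = rc.fit_jmle(m)
    return m, factors, truth, params


@pytest.fixture()
def toy_matrix():
    """4 persons × 3 items, 3 categories, mixed scores, no extremes."""
    vals = np.array([[1, 2, 2], [2, 3, 2], [2, 2, 3], [3, 2, 1]])
    return rc.ResponseMatrix(vals, tuple("ABCD"), ("i1", "i2", "i3"), 3)


@pytest.fixture()
def tight_settings():
    return EstimationSettings(convergence_tol=1e-7, max_iterations=2000)
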