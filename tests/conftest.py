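import numpy as np
import pandas as pd
import pytest
from scipy import special

from listlength.glmm import LogisticGLMM
from listlength.simulate import SimulationConfig, default_coefficients, simulate_records


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture
def toy_records():
    """Nine record rows forming four candidate lists across two counties."""
    rows = [
        # one list with a repeated species (L=2, records=3)
        ("A", 1950, 6, 10, "alpha-site1", "Alpha", "smith"),
        ("A", 1950, 6, 10, "alpha-site1", "Alpha", "smith"),
        ("B", 1950, 6, 10, "alpha-site1", "Alpha", "smith"),
        # same locality/date, different collector -> separate list (L=1)
        ("B", 1950, 6, 10, "alpha-site1", "Alpha", "jones"),
        # year-only date forms its own key
        ("C", 1960, None, None, "beta-site2", "Beta", "smith"),
        ("D", 1960, None, None, "beta-site2", "Beta", "smith"),
        # three-species list
        ("A", 1970, 7, 4, "beta-site1", "Beta", "doe"),
        ("C", 1970, 7, 4, "beta-site1", "Beta", "doe"),
        ("D", 1970, 7, 4, "beta-site1", "Beta", "doe"),
    ]
    return pd.DataFrame(
        rows, columns=["species", "year", "month", "day", "locality", "county", "collector"]
    )


def make_glmm_data(seed, n=120, n_groups=5, beta=(0.2, 0.8, -0.5), sd=0.7):
    """Small simulated mixed-logit dataset with known parameters."""
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, dtype=float)
    X = rng.normal(size=(n, len(beta) - 1))
    groups = rng.integers(0, n_groups, size=n)
    b = rng.normal(0, sd, size=n_groups)
    eta = beta[0] + X @ beta[1:] + b[groups]
    y = (rng.random(n) < special.expit(eta)).astype(float)
    return y, X, groups


@pytest.fixture
def toy_glmm():
    y, X, groups = make_glmm_data(7)
    return LogisticGLMM(y, X, groups)


@pytest.fixture(scope="session")
def small_simulation():
    """A small but fully structured simulated dataset shared across tests."""
    config = SimulationConfig(
        n_counties=6,
        n_species=3,
        n_events=400,
        seed=42,
        true_coefficients=default_coefficients(3),
    )
    records, truth = simulate_records(config)
    return config, records, truth
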