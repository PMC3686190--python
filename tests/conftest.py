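import numpy as np
import pandas as pd
import pytest

import ecominima as em
from ecominima.layers import VariableTable

# Eigenvalue ladder published for a 27-variable sage-grouse niche model
# (bootstrap-averaged partitioned D2); used as a diagnostics fixture.
LADDER_27 = np.array([
    3.85, 2.98, 2.36, 1.85, 1.70, 1.48, 1.29, 1.18, 1.11, 1.01,
    0.94, 0.86, 0.81, 0.75, 0.67, 0.56, 0.53, 0.49, 0.46, 0.43,
    0.40, 0.32, 0.29, 0.23, 0.21, 0.13, 0.11,
])


@pytest.fixture(scope="session")
def ladder27() -> np.ndarray:
    return LADDER_27.copy()


@pytest.fixture(scope="session")
def landscape():
    """Small planted landscape shared across tests: stack, niche, layout."""
    cfg = em.LandscapeConfig(n_rows=64, n_cols=64, p=10, corr_length=3.0, seed=1)
    niche = em.random_niche(10, 2, seed=2, sigma_min=0.1, sigma_free=1.0,
                            presence_quantile=0.25)
    layout = em.default_layout(cfg, n_pops=3, leks_per_pop=120, seed=3)
    stack = em.gen_env_stack(cfg, niche, layout)
    return cfg, niche, layout, stack


@pytest.fixture(scope="session")
def occurrences(landscape):
    _, niche, layout, stack = landscape
    return em.gen_occurrences(stack, niche, layout, seed=4)


@pytest.fixture(scope="session")
def gauss_table():
    """Correlated Gaussian variable table, n=500, p=10 (no spatial part)."""
    rng = np.random.default_rng(42)
    A = rng.normal(size=(10, 10))
    X = rng.normal(size=(500, 10)) @ A.T + rng.normal(size=10)
    cols = [f"v{i}" for i in range(10)]
    return VariableTable(data=pd.DataFrame(X, columns=cols),
                         provenance={c: (c, "point", 0.0) for c in cols})


@pytest.fixture(scope="session")
def single_model(gauss_table):
    return em.fit_single(gauss_table)
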