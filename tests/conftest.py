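import numpy as np
import pandas as pd
import pytest

from nichecast import (SimulationSpec, sample_occurrences, simulate_stack,
                       simulate_vectors, true_suitability)


@pytest.fixture(scope="session")
def small_spec():
    return SimulationSpec(grid_shape=(60, 60), n_layers=4, n_presences=120,
                          true_coefficients={"env1": 1.5, "env2": -1.0}, seed=11)


@pytest.fixture(scope="session")
def small_stack(small_spec):
    return simulate_stack(small_spec)


@pytest.fixture(scope="session")
def small_truth(small_spec, small_stack):
    return true_suitability(small_stack, small_spec)


@pytest.fixture(scope="session")
def small_occs(small_spec, small_truth):
    return sample_occurrences(small_truth, small_spec.n_presences, seed=12)


@pytest.fixture(scope="session")
def small_vectors(small_spec):
    return simulate_vectors(small_spec)


@pytest.fixture(scope="session")
def uniform_tables():
    """Uniform background and a Gibbs-weighted presence sample."""
    rng = np.random.default_rng(99)
    n = 1000
    bg = pd.DataFrame({"a": rng.uniform(0, 1, n), "b": rng.uniform(0, 1, n)})
    eta = np.array([2.0, -1.5])
    w = np.exp(bg.to_numpy() @ eta)
    w /= w.sum()
    pres = bg.iloc[rng.choice(n, size=150, p=w)].reset_index(drop=True)
    return pres, bg
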