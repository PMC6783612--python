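import numpy as np
import pytest

import connectokit as ck


def fa_matrix(adjacency, weight=0.5):
    """Symmetric FA matrix from a 0/1 adjacency (upper triangle honored)."""
    a = np.triu(np.asarray(adjacency, dtype=float), 1) * weight
    return a + a.T


def random_fa_matrix(n, density, rng):
    """Random symmetric FA-weighted matrix with weights in (0.1, 0.9)."""
    iu = np.triu_indices(n, 1)
    w = np.zeros((n, n))
    present = rng.random(len(iu[0])) < density
    w[iu] = np.where(present, rng.uniform(0.1, 0.9, len(iu[0])), 0.0)
    return w + w.T


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_config():
    """A fast, fully planted small-cohort configuration."""
    return ck.SimulationConfig(
        n_nodes=40, n_patients=8, n_controls=9, degree_sd=8.0,
        planted_component=[(0, 1), (0, 2), (0, 3)], fa_effect=0.12,
        degree_deficit_nodes=[10, 11], edge_removal_prob=0.3,
        clinical_rho=-0.5, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return ck.generate_cohort(small_config)
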