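import numpy as np
import pytest
from hypothesis import settings

from dtiwalk import synthetic

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def tiny_bundle():
    """A small planted-signal dataset shared by pipeline-level tests."""
    spec = synthetic.SyntheticSpec(
        n_drugs=40,
        n_proteins=50,
        n_diseases=60,
        n_side_effects=40,
        latent_dim=4,
        interaction_density=0.05,
        profile_noise=0.0,
        isolated_fraction=0.1,
        seed=7,
    )
    return synthetic.generate(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_weighted_graph(rng, n=None, p=None):
    """Random symmetric non-negative weight matrix with zero diagonal
    (Erdos-Renyi support, uniform [0,1] weights)."""
    if n is None:
        n = int(rng.integers(5, 51))
    if p is None:
        p = float(rng.uniform(0.1, 0.9))
    support = rng.random((n, n)) < p
    weights = rng.random((n, n))
    W = np.where(support, weights, 0.0)
    W = np.triu(W, k=1)
    return W + W.T
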