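import numpy as np
import pytest

from mdselect import ExpressionDataset, SimSpec, simulate
from mdselect.synthetic import fixture_suite


@pytest.fixture(scope="session")
def suite():
    return fixture_suite()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_dataset(rng, n_max=20, g_max=15):
    """A small random two-class dataset with occasional ties (rounded values)."""
    n0 = int(rng.integers(2, n_max // 2 + 1))
    n1 = int(rng.integers(2, n_max // 2 + 1))
    g = int(rng.integers(1, g_max + 1))
    values = rng.standard_normal((n0 + n1, g))
    if rng.random() < 0.3:  # induce ties
        values = np.round(values, 1)
    labels = np.array([0] * n0 + [1] * n1)
    return ExpressionDataset(
        values=values, labels=labels, gene_ids=[f"g{j}" for j in range(g)]
    )


@pytest.fixture(scope="session")
def separable():
    """Strongly separable synthetic data: 5 planted genes at 10 SDs."""
    data, truth = simulate(
        SimSpec(n0=20, n1=20, n_genes=100, n_informative=5, effect=10.0, seed=3)
    )
    return data, truth
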