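import numpy as np
import pytest

from serumcmp.expression import CountMatrix
from serumcmp.synthetic_data import SimulationConfig, simulate_dhs, simulate_expression


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_genes=400, n_windows=200, n_alignment_genes=60, seed=11
    )


@pytest.fixture(scope="session")
def expression_fixture(small_config):
    return simulate_expression(small_config)


@pytest.fixture(scope="session")
def dhs_fixture(small_config):
    return simulate_dhs(small_config)


@pytest.fixture()
def two_group_null():
    """2 groups x 4 replicates of null NB counts (mu=100, phi=0.1)."""
    rng = np.random.default_rng(7)
    g, phi, mu, n = 300, 0.1, 100.0, 8
    lam = rng.gamma(1 / phi, mu * phi, size=(g, n))
    y = rng.poisson(lam)
    samples = [("A", "T0", f"r{j}") if j < 4 else ("B", "T0", f"r{j}") for j in range(n)]
    return CountMatrix([f"g{i:04d}" for i in range(g)], samples, y), ["A"] * 4 + ["B"] * 4
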