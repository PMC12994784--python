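"""Shared fixtures: small simulated panels and toy regression problems."""

import numpy as np
import pytest

from bayesgp import GenotypeMatrix, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_panel():
    """A 120 x 60 panel with sparse architecture, reused across tests."""
    cfg = SimulationConfig(
        n_individuals=120,
        n_markers=60,
        n_causal=4,
        heritability_target=0.5,
        polygenic_fraction=0.2,
        ld_block_size=10,
        n_subpops=2,
        seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def toy_regression():
    """n=40, p=5 dense Gaussian design with two real effects."""
    rng = np.random.default_rng(7)
    X = rng.normal(size=(40, 5))
    beta = np.array([1.2, -0.8, 0.0, 0.0, 0.0])
    y = X @ beta + rng.normal(0, 0.7, 40)
    return X, y, beta


@pytest.fixture()
def tiny_genotypes():
    """Hand-sized dosage matrix with ids."""
    dosages = np.array([[0, 1, 2], [1, 1, 0], [2, 0, 1], [0, 2, 2]])
    return GenotypeMatrix(dosages, [f"s{i}" for i in range(4)], ["a", "b", "c"])
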