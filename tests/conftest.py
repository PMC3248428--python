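from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from preylink.io import SpectralCountMatrix
from preylink.synthetic import GeneratorConfig, generate


def random_matrix(
    n_proteins: int, n_experiments: int, seed: int, zero_fraction: float = 0.5,
    max_count: int = 20,
) -> SpectralCountMatrix:
    """Dense random count matrix with a controlled sparsity level."""
    rng = np.random.default_rng(seed)
    counts = rng.integers(1, max_count + 1, size=(n_proteins, n_experiments))
    counts[rng.random((n_proteins, n_experiments)) < zero_fraction] = 0
    proteins = [f"P{i:03d}" for i in range(n_proteins)]
    experiments = [f"E{j:03d}" for j in range(n_experiments)]
    mw = pd.Series(rng.uniform(10, 200, size=n_proteins), index=proteins)
    return SpectralCountMatrix(
        spc=pd.DataFrame(counts, index=proteins, columns=experiments), mw=mw
    )


@pytest.fixture
def small_matrix() -> SpectralCountMatrix:
    return random_matrix(12, 8, seed=7)


@pytest.fixture(scope="session")
def default_dataset():
    """The reference synthetic compendium (default generator settings)."""
    return generate(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """A scaled-down compendium for fast integration tests."""
    cfg = GeneratorConfig(
        seed=3,
        n_proteins=150,
        n_complexes=6,
        complex_size_range=(3, 10),
        n_experiments=40,
        list_size_range=(15, 50),
        n_sticky=8,
        n_antibodies=18,
        n_decoy_domains=40,
    )
    return cfg, generate(cfg)
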