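import numpy as np
import pandas as pd
import pytest

import streamdisturb as sd


@pytest.fixture(scope="session")
def default_config():
    return sd.GeneratorConfig(seed=11)


@pytest.fixture(scope="session")
def landscape(default_config):
    return sd.generate_landscape(default_config)


@pytest.fixture(scope="session")
def assemblage(landscape, default_config):
    matrix, attrs, truth = sd.generate_assemblage(landscape, default_config)
    return matrix, attrs, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_abundance(rng, n_sites=10, n_species=15, lam=4.0) -> pd.DataFrame:
    """Random count matrix with every site occupied."""
    counts = rng.poisson(lam, size=(n_sites, n_species))
    empty = counts.sum(axis=1) == 0
    counts[empty, 0] = 1
    return pd.DataFrame(
        counts,
        index=[f"s{i}" for i in range(n_sites)],
        columns=[f"sp{j}" for j in range(n_species)],
    )
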