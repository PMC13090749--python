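import numpy as np
import pytest

from ednacongruence.simulate import SimulationConfig, generate_collection


@pytest.fixture(scope="session")
def default_collection():
    """The default 50-dataset synthetic collection (seed 0) plus truth."""
    return generate_collection(SimulationConfig())


@pytest.fixture(scope="session")
def small_collection():
    """A 10-dataset collection for cheap structural tests."""
    import dataclasses
    cfg = dataclasses.replace(SimulationConfig(), n_datasets=10, seed=11)
    return generate_collection(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_read_table(rng, n_species=None, n_sites=None, dataset_id="T"):
    """Random integer read table with positive site totals."""
    import pandas as pd
    from ednacongruence.congruence import ReadTable

    n_species = n_species or int(rng.integers(2, 12))
    n_sites = n_sites or int(rng.integers(1, 8))
    counts = rng.integers(0, 50, size=(n_species, n_sites))
    for j in range(n_sites):  # ensure positive site totals
        if counts[:, j].sum() == 0:
            counts[int(rng.integers(n_species)), j] = 1
    idx = [f"Genus{i} sp{i}" for i in range(n_species)]
    return ReadTable(dataset_id, pd.DataFrame(
        counts, index=pd.Index(idx, name="species"),
        columns=[f"s{j}" for j in range(n_sites)]))
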