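import numpy as np
import pytest

from idrfuse.features import fit_aaindex_reducer, load_energy_tables, synthetic_aaindex_profiles
from idrfuse.simulate import SimulationParams, simulate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small but structured synthetic dataset for plumbing tests."""
    params = SimulationParams(n_proteins=12, length_range=(20, 40), seed=7)
    return simulate_dataset(params)


@pytest.fixture(scope="session")
def reducer():
    return fit_aaindex_reducer(synthetic_aaindex_profiles())


@pytest.fixture(scope="session")
def energy_tables():
    return load_energy_tables()
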