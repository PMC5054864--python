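import numpy as np
import pytest

from myxogeo.design import sample_sheet_from_ids
from myxogeo.pairs import sample_independent_pairs
from myxogeo.simulate import simulate_landscape


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic landscape shared across the session."""
    return simulate_landscape(seed=101)


@pytest.fixture(scope="session")
def default_pairs(default_sim):
    return sample_independent_pairs(default_sim.sample_sheet, seed=202)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def minimal_design_ids():
    """Exactly one disjoint pair per scale is available (capacity = demand
    for n_per_scale=1, n_replicates=1)."""
    return [
        "SA1.1.1A", "SA1.1.1B",  # micrometre
        "SA1.1.2A", "SA1.1.3A",  # millimetre
        "SA1.2.1A", "SA1.3.1A",  # centimetre
        "SA2.1.1A", "SA3.1.1A",  # metre
        "SB1.1.1A", "SC1.1.1A",  # kilometre
    ]


@pytest.fixture
def minimal_sheet():
    return sample_sheet_from_ids(minimal_design_ids())


def random_sequences(rng, n, length, alphabet="ACGT"):
    letters = np.array(list(alphabet))
    return ["".join(letters[rng.integers(0, len(letters), length)]) for _ in range(n)]
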