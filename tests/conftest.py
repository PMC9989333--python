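import numpy as np
import pytest

from mutspectra.demography import Epoch, Population, PopulationModel, build_basic_model
from mutspectra.mutation_model import build_uniform_matrix, normalize_overall_rate
from mutspectra.sequence import generate_sequence
from mutspectra.simulator import simulate_dataset

UNIFORM = (0.25, 0.25, 0.25, 0.25)


@pytest.fixture(scope="session")
def uniform_seq():
    """100 kb uniform-composition synthetic ancestral sequence."""
    return generate_sequence(100_000, UNIFORM, seed=101)


@pytest.fixture(scope="session")
def norm_matrix(uniform_seq):
    return normalize_overall_rate(build_uniform_matrix(), uniform_seq, 1e-8)


@pytest.fixture(scope="session")
def constant_model():
    return build_basic_model("constant")


@pytest.fixture(scope="session")
def single_pop_model():
    return PopulationModel(populations=(Population("p", (Epoch(0.0, 10_000),)),))


@pytest.fixture(scope="session")
def two_pop_table(constant_model, uniform_seq, norm_matrix):
    """One simulated dataset: 20+20 diploids, 100 kb, constant basic model."""
    return simulate_dataset(
        constant_model, uniform_seq, norm_matrix,
        {"ancestral": 40, "derived": 40}, window_length=10_000, seed=202,
    )
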