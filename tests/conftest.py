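"""Shared fixtures: fixture databank, toy complex, transferred models.

Expensive artifacts (toy-complex transfer, the default-grid energy table)
are session-scoped so the suite builds them once.
"""

import numpy as np
import pytest
from hypothesis import settings

from epmm import (
    QuadratureSpec,
    make_fixture_databank,
    make_toy_complex,
    partition_fragments,
    residue_energy_table,
    scale_fragment_charges,
    transfer_parameters,
)
from epmm.synthetic import ToyComplexSpec

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def databank():
    return make_fixture_databank()


@pytest.fixture(scope="session")
def toy():
    """(structure, charge plan) of the default toy complex."""
    return make_toy_complex(ToyComplexSpec(seed=0))


@pytest.fixture(scope="session")
def toy_model(toy, databank):
    """(scaled model, H-extended structure, charge plan)."""
    structure, plan = toy
    model, extended = transfer_parameters(structure, databank)
    scaled = scale_fragment_charges(model, extended, plan)
    return scaled, extended, plan


@pytest.fixture(scope="session")
def toy_partition(toy_model):
    _, extended, _ = toy_model
    return partition_fragments(extended)


@pytest.fixture(scope="session")
def toy_report(toy_model, toy_partition):
    scaled, extended, _ = toy_model
    return residue_energy_table(
        scaled, extended, toy_partition, QuadratureSpec(), label="toy-seed0"
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
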