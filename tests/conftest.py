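import pytest

import oligomob as om
from oligomob.simulate import (
    intact_mz1580_config,
    quad_mz1580_config,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def phf6():
    return om.AC_PHF6_NH2


@pytest.fixture(scope="session")
def phf6_comp(phf6):
    return om.composition_of(phf6)


@pytest.fixture(scope="session")
def M(phf6_comp):
    return om.monoisotopic_mass(phf6_comp)


@pytest.fixture(scope="session")
def mz1580_family(M):
    return om.isobaric_family(1580.0, 0.5, M, n_max=12, z_max=6)


@pytest.fixture(scope="session")
def quad1580_dataset():
    dataset, truth = simulate_dataset(quad_mz1580_config(seed=0))
    return dataset, truth


@pytest.fixture(scope="session")
def intact_reference_dataset():
    dataset, truth = simulate_dataset(intact_mz1580_config(seed=0))
    return dataset, truth
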