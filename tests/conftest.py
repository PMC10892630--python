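import numpy as np
import pytest

from colchigen.corpus import CellLine
from colchigen.descriptors import NAMED_DESCRIPTORS, compute_descriptors
from colchigen.fixtures import (
    FixtureSpec,
    make_fixture_library,
    make_fragment_table,
    make_synthetic_activity,
)

# The two starting structures and three generated analogs whose printed
# similarity values calibrate the fingerprint dialect.
START_1 = "COc2c3C1=CC=C(SC)C(=O)C=C1[C@H](CCc3cc(OC)c2OC)NCC"
START_2 = "CC(CC)N[C@H]2CCc3cc(OC)c(OC)c(OC)c3C1=CC=C(NC)C(=O)C=C12"
NEW_AMINE = "COC1=C2C3=CC=C(NC)C(=O)C=C3[C@H1](CCC2=CC(OC)=C1OC)NCCONC"
NEW_CHLORO = "COC1=C2C3=CC=C(SC)C(=O)C=C3[C@H1](CCC2=CC(OC)=C1OC)NCCCCl"
NEW_FLUORO = "N([C@H1]1CCC2=CC(OC)=C(OC)C(OC)=C2C3=CC=C(NC)C(C=C31)=O)CCCCF"


@pytest.fixture(scope="session")
def library():
    """Default 120-analog fixture library (all S-configured)."""
    return make_fixture_library(FixtureSpec(n_molecules=120, seed=15))


@pytest.fixture(scope="session")
def small_library():
    return make_fixture_library(FixtureSpec(n_molecules=20, seed=15))


@pytest.fixture(scope="session")
def mixed_stereo_library():
    return make_fixture_library(
        FixtureSpec(n_molecules=120, seed=15, r_fraction=0.25, undefined_fraction=0.1)
    )


@pytest.fixture(scope="session")
def fragment_table(library):
    return make_fragment_table(library, seed=0)


@pytest.fixture(scope="session")
def named_descriptors(library):
    return compute_descriptors(library, names=list(NAMED_DESCRIPTORS))


@pytest.fixture(scope="session")
def synthetic_activity(library):
    """Activities at the reference noise level (sigma = 0.1 sd(signal))."""
    _, truth0 = make_synthetic_activity(library, sigma=0.0, seed=42)
    signal = truth0.descriptor_values.to_numpy() @ np.array(list(truth0.betas.values()))
    sigma = 0.1 * float(np.std(signal))
    return make_synthetic_activity(library, sigma=sigma, seed=42)


@pytest.fixture(scope="session")
def pic50_vector(library, synthetic_activity, named_descriptors):
    records, _ = synthetic_activity
    by_id = {r.molecule.id: r for r in records}
    ids = list(named_descriptors.values.index)
    return np.array([by_id[i].pic50[CellLine.A549] for i in ids])
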