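import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # for the shared oracles module

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from splitgas.gas import GASPartition
from splitgas.integrals import make_hubbard, make_random_integrals


@pytest.fixture(scope="session")
def hubbard_dimer():
    return make_hubbard(2, 1.0, 4.0)


@pytest.fixture(scope="session")
def cas44_integrals():
    """Random diagonally dominated CAS(4,4) set used by several modules."""
    return make_random_integrals(4, 4, seed=11)


@pytest.fixture(scope="session")
def table1_partition():
    """3 electrons in 3 subspaces, local {N_min=[0,0,1], N_max=[2,2,2]}."""
    return GASPartition.from_sizes([2, 2, 2], [0, 0, 1], [2, 2, 2], "local", 3)


@pytest.fixture(scope="session")
def splitgas_cas66():
    """CAS(6,6)-style three-subspace model with a G3-empty principal space."""
    ints = make_random_integrals(6, 6, seed=21)
    gas_t = GASPartition.from_sizes([2, 2, 2], [0, 0, 0], [4, 4, 4], "local", 6)
    gas_p = GASPartition.from_sizes([2, 2, 2], [2, 0, 0], [4, 4, 0], "local", 6)
    return ints, gas_t, gas_p
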