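import numpy as np
import pytest

from nanoweld.structure import AtomicStructure, build_periodic_tube


@pytest.fixture(scope="session")
def tube44():
    """Pristine (4,4) armchair cell: 16 atoms, metallic."""
    return build_periodic_tube((4, 4))


@pytest.fixture(scope="session")
def tube130():
    """Pristine (13,0) zigzag cell: 52 atoms, semiconducting."""
    return build_periodic_tube((13, 0))


@pytest.fixture()
def dimer():
    """Two carbons one bond apart along z: the 2x2 closed-form fixture."""
    st = AtomicStructure(
        positions=np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.142]]),
        elements=["C", "C"],
    )
    st.rebuild_bonds()
    return st
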