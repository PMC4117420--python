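import numpy as np
import pytest

from hydrofilm import spin_model


@pytest.fixture(scope="session")
def table_p3():
    """Interaction table with both P6 and metastable P3 ordering allowed."""
    return spin_model.build_interaction_table(p3_enabled=True)


@pytest.fixture(scope="session")
def table_p6():
    """Interaction table with only P6 ordering allowed."""
    return spin_model.build_interaction_table(p3_enabled=False)


@pytest.fixture(scope="session")
def neutral_table():
    """A table with every orientation pair allowed (used with zero couplings
    to realize a non-interacting adsorption/desorption process)."""
    cls = np.full((6, 6, 6), spin_model.P6DOCK, dtype=np.uint8)
    for d, s, t in spin_model._trimer_triples():
        cls[d, s, t] = spin_model.TRIMER
    return spin_model.InteractionTable(cls=cls, p3_enabled=True)


@pytest.fixture(scope="session")
def default_params():
    return spin_model.ModelParams()
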