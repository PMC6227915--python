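import numpy as np
import pytest

from popfert import synthetic


@pytest.fixture(scope="session")
def small_truth():
    """A 1950-1990 country with mild migration, shared across tests."""
    sc = synthetic.CountryScenario(year_start=1950, year_end=1990,
                                   mig_rate=0.001)
    return synthetic.make_true_country(sc, seed=3)


@pytest.fixture(scope="session")
def lifetable_library():
    return synthetic.make_lifetable_library(60, seed=7)


@pytest.fixture(scope="session")
def zero_mortality_table():
    from popfert.lifetables import CompleteLifeTable
    qx = np.zeros(111)
    qx[110] = 1.0
    return CompleteLifeTable.from_qx(qx, a0=0.5, a_term=5.0)
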