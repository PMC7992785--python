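import numpy as np
import pytest

from nashburden import (
    HealthState,
    LifeTable,
    ParameterSet,
)
from nashburden.param_store import parameters_to_dict, parameters_from_dict
from nashburden.synthetic_data import (
    base_parameter_set,
    default_life_table,
    default_population,
)


@pytest.fixture(scope="session")
def base_ps() -> ParameterSet:
    return base_parameter_set()


@pytest.fixture(scope="session")
def population():
    return default_population()


@pytest.fixture(scope="session")
def life_table() -> LifeTable:
    return default_life_table()


@pytest.fixture(scope="session")
def zero_asmr_table() -> LifeTable:
    """A life table with zero background mortality at every age."""
    ages = np.arange(18, 111)
    return LifeTable(ages=ages, q=np.zeros_like(ages, dtype=float))


@pytest.fixture()
def ps_dict(base_ps):
    """A fresh mutable dict form of the base case, for corruption tests."""
    return parameters_to_dict(base_ps)


def rebuild(doc: dict) -> ParameterSet:
    return parameters_from_dict(doc)
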