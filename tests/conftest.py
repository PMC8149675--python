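import numpy as np
import pytest

from scdcea.engine import WaningSpec, build_model_inputs, run_strategies
from scdcea.mortality import LifeTable, default_life_tables
from scdcea.parameters import default_parameters


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def inputs(params):
    return build_model_inputs(params)


@pytest.fixture(scope="session")
def tables():
    return default_life_tables()


@pytest.fixture(scope="session")
def base_results(inputs, tables):
    """Lifetime-durability base case, all arms and strata, with traces."""
    return run_strategies(inputs, tables, WaningSpec.lifetime(), keep_trace=True)


@pytest.fixture
def flat_table():
    """Constant 2%/year mortality, ages 0..100."""
    qx = np.full(101, 0.02)
    qx[-1] = 1.0
    return LifeTable(qx, label="flat")


@pytest.fixture
def immortal_table():
    """No mortality before the terminal age."""
    qx = np.zeros(101)
    qx[-1] = 1.0
    return LifeTable(qx, label="immortal")
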