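import warnings

import pytest

from sfeperf import datasets
from sfeperf.design import FactorSpec


@pytest.fixture(scope="session")
def frame():
    """The packaged 20-run design with measured responses."""
    return datasets.load_design_response()


@pytest.fixture(scope="session")
def table():
    return datasets.load_design_table()


@pytest.fixture(scope="session")
def factors():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return datasets.paper_factors()


@pytest.fixture(scope="session")
def cost_cfg():
    return datasets.load_cost_config()


@pytest.fixture(scope="session")
def chemicals():
    return datasets.load_chemicals()


@pytest.fixture
def toy_factors():
    """Symmetric unit factors for synthetic-design tests."""
    return [
        FactorSpec("f1", "u", 0.0, 1.0, -1.5, 1.5),
        FactorSpec("f2", "u", 0.0, 1.0, -1.5, 1.5),
        FactorSpec("f3", "u", 0.0, 1.0, -1.5, 1.5),
    ]
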