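import numpy as np
import pytest

from driftrar import (
    DesignSpec,
    PolicyConfig,
    ScenarioSpec,
    build_gi_table,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def gi_table_small():
    """Shallow, cheaply built table for unit tests of the index rules."""
    return build_gi_table(max_depth=24, discount=0.9, tol=1e-6)


@pytest.fixture(scope="session")
def gi_table_full():
    """Production-scale table (discount 0.995) covering trials up to T=200;
    built once per session and shared by the operating-characteristics
    tests."""
    return build_gi_table(max_depth=200, discount=0.995, tol=2.0**-10)


@pytest.fixture
def design_2arm():
    return DesignSpec(K=1, T=100, J=5, b=20)


@pytest.fixture
def null_scenario_2arm(design_2arm):
    return ScenarioSpec.standard_of_care(design_2arm, p0=0.3, D=0.0)
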