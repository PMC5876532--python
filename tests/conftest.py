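import numpy as np
import pandas as pd
import pytest

from exprdriver import (
    CallerParams,
    ExpressionMatrix,
    MutationMatrix,
    call_functional_mutations,
)
from exprdriver.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The reference simulated cohort (300 patients, 5 planted drivers)."""
    return simulate_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def default_calls(default_cohort):
    """Functional calls on the reference cohort under default parameters."""
    return call_functional_mutations(
        default_cohort.expression, default_cohort.mutations, CallerParams()
    )


@pytest.fixture()
def toy_expr():
    """3 features x 4 patients with simple hand-checkable values."""
    data = pd.DataFrame(
        [
            [1.0, 2.0, 3.0, 4.0],
            [2.0, 4.0, 6.0, 8.0],
            [4.0, 3.0, 2.0, 1.0],
        ],
        index=["fA", "fB", "fC"],
        columns=["P1", "P2", "P3", "P4"],
    )
    return ExpressionMatrix(data)


@pytest.fixture()
def toy_mut():
    data = pd.DataFrame(
        [
            [1, 0, 1, 0],
            [0, 1, 1, 0],
            [1, 1, 0, 1],
        ],
        index=["gA", "gB", "gC"],
        columns=["P1", "P2", "P3", "P4"],
        dtype=np.int8,
    )
    return MutationMatrix(data)


def pytest_configure(config):
    try:
        from hypothesis import settings

        settings.register_profile("ci", derandomize=True, max_examples=50)
        settings.load_profile("ci")
    except ImportError:
        pass
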