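import numpy as np
import pytest

from interpsurv import (
    EventData,
    LifeTable,
    SimulationSpec,
    example_fixtures,
    simulate_event_data,
)

import pandas as pd


@pytest.fixture(scope="session")
def fixtures():
    """Worked-example coordinate bundle (deterministic seed)."""
    return example_fixtures()


@pytest.fixture(scope="session")
def exp_data():
    """300 uncensored draws from an exponential with rate 0.5."""
    return simulate_event_data(
        SimulationSpec("exponential", (0.5,), n=300, seed=42)
    )


@pytest.fixture()
def flat_life_table():
    """Life table with constant annual hazard 0.02 at every age and sex."""
    qx = -np.expm1(-0.02)
    rows = []
    for sex in ("female", "male"):
        rows.append(pd.DataFrame({"age": range(0, 111), "sex": sex, "qx": qx}))
    return LifeTable.from_frame(pd.concat(rows, ignore_index=True))


@pytest.fixture()
def tiny_data():
    return EventData(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 0]))
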