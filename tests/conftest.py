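import numpy as np
import pytest

from cssaflow import (
    AgeGrid,
    BirthSchedule,
    StateDistribution,
    SyntheticConfig,
    TransitionSchedule,
    generate_synthetic_inputs,
    load_reference_schedule,
)


@pytest.fixture(scope="session")
def ref_schedule() -> TransitionSchedule:
    """Packaged Hong Kong CSSA 2014-15 decadal schedule, expanded to ages 0-59."""
    return load_reference_schedule()


@pytest.fixture(scope="session")
def synth():
    """One fixed synthetic input set (ts, bs, pw, x0) used across tests."""
    return generate_synthetic_inputs(SyntheticConfig(seed=7))


@pytest.fixture()
def toy3():
    """Tiny 3-age system with hand-checkable dynamics.

    b is supported on age 1 only (the fertile window is declared as (1, 1)
    for this toy), so the newborn proportion equals x(1).
    """
    grid = AgeGrid(3)
    ts = TransitionSchedule(p=[0.1, 0.2, 0.3], q=[0.3, 0.2, 0.1], grid=grid)
    bs = BirthSchedule(b=[0.0, 0.1, 0.0], grid=grid, fertile_range=(1, 1))
    x = StateDistribution([0.2, 0.5, 0.8], grid)
    return grid, ts, bs, x
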