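import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cosmos_kinetics import (
    AcquisitionSchedule,
    ConstructSpec,
    FIVE_I_THREE,
    THREE_E_FIVE,
    Interval,
    IntervalsTable,
    KineticModelParams,
    build_slide_layout,
    intervals_from_panel,
    simulate_panel,
)


@pytest.fixture(scope="session")
def schedule():
    return AcquisitionSchedule()


@pytest.fixture(scope="session")
def short_schedule():
    return AcquisitionSchedule(total_duration=300.0)


@pytest.fixture(scope="session")
def default_params():
    return KineticModelParams()


@pytest.fixture(scope="session")
def two_construct_panel(schedule, default_params):
    """A small simulated experiment with two RNA species plus controls."""
    layout = build_slide_layout(
        {"5i3": 40, "3e5": 40}, n_controls=40, seed=11
    )
    return simulate_panel(
        layout,
        default_params,
        schedule,
        seed=11,
        panel=[FIVE_I_THREE, THREE_E_FIVE],
    )


@pytest.fixture(scope="session")
def two_construct_table(two_construct_panel):
    return intervals_from_panel(two_construct_panel)


def make_table(dwells_by_loc, constructs, schedule=None, start=10.0):
    """Hand-build an IntervalsTable from per-location dwell lists."""
    sched = schedule or AcquisitionSchedule()
    intervals = []
    meta = []
    for lid, dwells in dwells_by_loc.items():
        t = start
        for d in dwells:
            intervals.append(Interval(lid, t, t + d))
            t += d + 20.0
        meta.append(
            {
                "location_id": lid,
                "construct": constructs[lid],
                "n_frames_observed": sched.n_green_frames(),
            }
        )
    return IntervalsTable(intervals, pd.DataFrame(meta), sched)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
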