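import numpy as np
import pytest
from shapely.geometry import LineString, box

from boarrest.landscape import HuntingCalendar, Landscape
from boarrest.simulate import SimulationConfig, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """2 animals x 40 days at default noise; reused by read-only tests."""
    return simulate_study(SimulationConfig(seed=11, n_animals=2,
                                           survey_length_days=40))


@pytest.fixture(scope="session")
def square_landscape():
    """Hand-built landscape: one 200x200 m village, one road, one veg patch."""
    village = box(1000, 1000, 1200, 1200)
    road = LineString([(0, 500), (5000, 500)])
    veg = box(3000, 3000, 4000, 4000)
    return Landscape(villages=[village], roads=[road], vegetation=[veg],
                     extent=(0, 0, 5000, 5000))


@pytest.fixture(scope="session")
def calendar_2021():
    """Seasons opening 15 Aug, closing end of Feb, around 2021."""
    return HuntingCalendar.default_for_years(
        [2019, 2020, 2021, 2022],
        bank_holidays=[np.datetime64("2021-11-01").astype("datetime64[D]").item()])
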