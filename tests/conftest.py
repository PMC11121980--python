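from datetime import date, datetime

import pytest

from windtrace.atmosphere import Domain, make_uniform_field
from windtrace.regions import demo_regions
from windtrace.solar import RUILI, FlightWindow


@pytest.fixture(scope="session")
def study_domain():
    return Domain(
        lat_min=16.0, lat_max=32.0, lon_min=88.0, lon_max=108.0,
        height_min=0.0, height_max=2000.0,
        time_start="2019-04-26T00:00:00", time_end="2019-04-29T00:00:00",
    )


@pytest.fixture(scope="session")
def uniform_east_grid(study_domain):
    """10 m/s eastward, calm meridional, 20 degC everywhere."""
    return make_uniform_field(10.0, 0.0, 20.0, study_domain)


@pytest.fixture(scope="session")
def fixture_regions():
    return demo_regions()


@pytest.fixture(scope="session")
def ruili():
    return RUILI


def make_window(start: datetime, hours: float) -> FlightWindow:
    """A synthetic flight window of exact duration (bypasses the ephemeris)."""
    from datetime import timedelta

    return FlightWindow(
        date=date(start.year, start.month, start.day),
        takeoff=start,
        landing_deadline=start + timedelta(hours=hours),
    )
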