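"""Solar ephemeris and nocturnal flight windows.

Migratory noctuid moths take off at dusk (peak about 20 min after sunset)
and land around dawn (peak about 10 min before the next sunrise), so each
simulated migration night runs from ``sunset + takeoff_offset`` to
``next sunrise - landing_offset``.  Sunrise/sunset come from the standard
NOAA solar-position computation with a zenith of 90.833 deg (refraction
plus the solar half-diameter), at sea level.

The computation keeps full seconds internally; round to minutes only for
presentation.  Polar latitudes (|lat| > 66.5 deg) are rejected rather than
handled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as _date
from datetime import datetime, timedelta

__all__ = ["Site", "FlightWindow", "sun_events", "flight_window", "RUILI"]

SUNRISE_SUNSET_ZENITH = 90.833  # deg: 34' refraction + 16' solar radius


class UnsupportedLatitudeError(ValueError):
    pass


@dataclass(frozen=True)
class Site:
    """A trap/release site with a fixed UTC offset (no DST handling)."""

    lat: float
    lon: float
    utc_offset: float
    name: str = ""

    def __post_init__(self) -> None:
        if abs(self.lat) > 66.5:
            raise UnsupportedLatitudeError(
                f"latitude {self.lat} is polar; sunrise/sunset undefined year-round"
            )
        if not -12.0 <= self.utc_offset <= 14.0:
            raise ValueError("utc_offset must lie in [-12, 14] hours")


#: The study's searchlight-trap site: Ruili, Dehong, Yunnan (decimal degrees;
#: the published coordinate string is read as 23.98 N, 97.83 E).
RUILI = Site(lat=23.98, lon=97.83, utc_offset=8.0, name="ruili")


@dataclass(frozen=True)
class FlightWindow:
    """One migration night: take-off instant and landing deadline."""

    date: _date
    takeoff: datetime
    landing_deadline: datetime
    takeoff_offset: timedelta = timedelta(minutes=20)
    landing_offset: timedelta = timedelta(minutes=10)

    def __post_init__(self) -> None:
        if self.takeoff >= self.landing_deadline:
            raise ValueError("takeoff must precede landing_deadline")

    @property
    def duration(self) -> timedelta:
        return self.landing_deadline - self.takeoff


# -- NOAA solar position ---------------------------------------------------


def _julian_day(d: _date, hours_utc: float) -> float:
    return d.toordinal() + 1721424.5 + hours_utc / 24.0


def _solar_geometry(jd: float):
    """Return (declination deg, equation of time minutes) at a Julian day."""
    T = (jd - 2451545.0) / 36525.0
    L0 = (280.46646 + T * (36000.76983 + 0.0003032 * T)) % 360.0
    M = 357.52911 + T * (35999.05029 - 0.0001537 * T)
    e = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)
    Mr = math.radians(M)
    C = (
        math.sin(Mr) * (1.914602 - T * (0.004817 + 0.000014 * T))
        + math.sin(2 * Mr) * (0.019993 - 0.000101 * T)
        + math.sin(3 * Mr) * 0.000289
    )
    true_long = L0 + C
    omega = math.radians(125.04 - 1934.136 * T)
    lam = math.radians(true_long - 0.00569 - 0.00478 * math.sin(omega))
    eps0 = 23.0 + (26.0 + (21.448 - T * (46.815 + T * (0.00059 - 0.001813 * T))) / 60.0) / 60.0
    eps = math.radians(eps0 + 0.00256 * math.cos(omega))
    decl = math.degrees(math.asin(math.sin(eps) * math.sin(lam)))
    y = math.tan(eps / 2.0) ** 2
    L0r = math.radians(L0)
    eot = 4.0 * math.degrees(
        y * math.sin(2 * L0r)
        - 2.0 * e * math.sin(Mr)
        + 4.0 * e * y * math.sin(Mr) * math.cos(2 * L0r)
        - 0.5 * y * y * math.sin(4 * L0r)
        - 1.25 * e * e * math.sin(2 * Mr)
    )
    return decl, eot


def _hour_angle(lat: float, decl: float, zenith: float) -> float:
    latr, declr = math.radians(lat), math.radians(decl)
    cos_h = (
        math.cos(math.radians(zenith)) / (math.cos(latr) * math.cos(declr))
        - math.tan(latr) * math.tan(declr)
    )
    if not -1.0 <= cos_h <= 1.0:
        raise UnsupportedLatitudeError(
            "sun does not cross the requested zenith on this date (polar regime)"
        )
    return math.degrees(math.acos(cos_h))


def _event_minutes_utc(site: Site, d: _date, rising: bool, zenith: float) -> float:
    # iterate: evaluate geometry at the previous estimate of the event time
    minutes = 720.0 - 4.0 * site.lon  # mean solar noon as starting guess
    for _ in range(3):
        decl, eot = _solar_geometry(_julian_day(d, minutes / 60.0))
        ha = _hour_angle(site.lat, decl, zenith)
        noon = 720.0 - 4.0 * site.lon - eot
        minutes = noon - 4.0 * ha if rising else noon + 4.0 * ha
    return minutes


def sun_events(
    site: Site, d: _date, zenith: float = SUNRISE_SUNSET_ZENITH
) -> tuple[datetime, datetime]:
    """Sunrise and sunset clock times (site local, fixed UTC offset)."""
    out = []
    for rising in (True, False):
        minutes_utc = _event_minutes_utc(site, d, rising, zenith)
        local = minutes_utc + site.utc_offset * 60.0
        out.append(
            datetime(d.year, d.month, d.day) + timedelta(minutes=local)
        )
    sunrise, sunset = out
    return sunrise, sunset


def flight_window(
    site: Site,
    d: _date,
    takeoff_offset: timedelta = timedelta(minutes=20),
    landing_offset: timedelta = timedelta(minutes=10),
) -> FlightWindow:
    """Nightly flight window: dusk take-off to the next dawn's deadline."""
    _, sunset = sun_events(site, d)
    next_sunrise, _ = sun_events(site, d + timedelta(days=1))
    return FlightWindow(
        date=d,
        takeoff=sunset + takeoff_offset,
        landing_deadline=next_sunrise - landing_offset,
        takeoff_offset=takeoff_offset,
        landing_offset=landing_offset,
    )
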