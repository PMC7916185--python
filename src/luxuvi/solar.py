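"""Solar position: zenith angle from location and time.

Implements the NOAA solar-calculator equations (Meeus-style low-accuracy
sun): Julian-century polynomials for the sun's mean longitude, mean anomaly
and obliquity, the equation of centre, then declination and the equation of
time, and finally the hour angle from true solar time.  Zenith accuracy is
a few hundredths of a degree over 1900-2100, far below the ~0.1 degree
sensitivity of the downstream UVI model.  Atmospheric refraction is not
applied: it matters only near the horizon, where UVI is effectively zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone

__all__ = [
    "SolarPosition",
    "solar_zenith",
    "solar_position",
    "solar_noon_utc",
    "equation_of_time",
    "solar_declination",
]


@dataclass(frozen=True)
class SolarPosition:
    """Sun geometry at one instant and ground location.

    Zenith is the angle from the local vertical in degrees (0 = overhead,
    90 = horizon, >90 = below horizon); declination is the sun's apparent
    celestial latitude in degrees.
    """

    timestamp_utc: datetime
    latitude: float
    longitude: float
    zenith: float
    declination: float

    @property
    def altitude(self) -> float:
        return 90.0 - self.zenith

    @property
    def is_daytime(self) -> bool:
        return self.zenith < 90.0


def _validate_coords(latitude: float, longitude: float) -> None:
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude {latitude!r} outside [-90, 90]")
    if not -180.0 <= longitude <= 180.0:
        raise ValueError(f"longitude {longitude!r} outside [-180, 180]")


def _to_utc(timestamp: datetime) -> datetime:
    if timestamp.tzinfo is None or timestamp.utcoffset() is None:
        raise ValueError("timestamp must carry an explicit UTC offset")
    return timestamp.astimezone(timezone.utc)


def _julian_centuries(t: datetime) -> float:
    """Julian centuries since J2000.0; t must already be UTC."""
    frac = (t.hour * 3600 + t.minute * 60 + t.second + t.microsecond / 1e6) / 86400.0
    jd = t.toordinal() + 1721424.5 + frac
    return (jd - 2451545.0) / 36525.0


def _sun_angles(T: float) -> tuple[float, float]:
    """(declination radians, equation of time minutes) at Julian century T."""
    rad = math.radians
    L0 = (280.46646 + T * (36000.76983 + 0.0003032 * T)) % 360.0
    M = 357.52911 + T * (35999.05029 - 0.0001537 * T)
    ecc = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)
    C = (
        (1.914602 - T * (0.004817 + 0.000014 * T)) * math.sin(rad(M))
        + (0.019993 - 0.000101 * T) * math.sin(rad(2 * M))
        + 0.000289 * math.sin(rad(3 * M))
    )
    omega = rad(125.04 - 1934.136 * T)
    app_long = L0 + C - 0.00569 - 0.00478 * math.sin(omega)
    eps0 = 23.0 + (26.0 + (21.448 - T * (46.815 + T * (0.00059 - 0.001813 * T))) / 60.0) / 60.0
    eps = rad(eps0 + 0.00256 * math.cos(omega))

    decl = math.asin(math.sin(eps) * math.sin(rad(app_long)))

    y = math.tan(eps / 2.0) ** 2
    eqtime = 4.0 * math.degrees(
        y * math.sin(2 * rad(L0))
        - 2.0 * ecc * math.sin(rad(M))
        + 4.0 * ecc * y * math.sin(rad(M)) * math.cos(2 * rad(L0))
        - 0.5 * y * y * math.sin(4 * rad(L0))
        - 1.25 * ecc * ecc * math.sin(2 * rad(M))
    )
    return decl, eqtime


def equation_of_time(timestamp: datetime) -> float:
    """Equation of time in minutes (apparent minus mean solar time)."""
    return _sun_angles(_julian_centuries(_to_utc(timestamp)))[1]


def solar_declination(timestamp: datetime) -> float:
    """Apparent solar declination in degrees."""
    return math.degrees(_sun_angles(_julian_centuries(_to_utc(timestamp)))[0])


def solar_position(latitude: float, longitude: float, timestamp: datetime) -> SolarPosition:
    """Compute the sun's zenith angle and declination.

    Parameters
    ----------
    latitude, longitude
        Site coordinates in degrees (east-positive longitude).
    timestamp
        Timezone-aware instant; converted to UTC internally.
    """
    _validate_coords(latitude, longitude)
    t = _to_utc(timestamp)
    decl, eqtime = _sun_angles(_julian_centuries(t))

    # True solar time in minutes from local midnight at the site's meridian.
    utc_minutes = t.hour * 60.0 + t.minute + t.second / 60.0 + t.microsecond / 6e7
    tst = (utc_minutes + eqtime + 4.0 * longitude) % 1440.0
    ha = math.radians(tst / 4.0 - 180.0)

    lat = math.radians(latitude)
    cos_zen = math.sin(lat) * math.sin(decl) + math.cos(lat) * math.cos(decl) * math.cos(ha)
    cos_zen = min(1.0, max(-1.0, cos_zen))
    return SolarPosition(
        timestamp_utc=t,
        latitude=latitude,
        longitude=longitude,
        zenith=math.degrees(math.acos(cos_zen)),
        declination=math.degrees(decl),
    )


def solar_zenith(latitude: float, longitude: float, timestamp: datetime) -> float:
    """Apparent solar zenith angle in degrees (0 = overhead, >90 = night)."""
    return solar_position(latitude, longitude, timestamp).zenith


def solar_noon_utc(latitude: float, longitude: float, date: datetime) -> datetime:
    """UTC instant of local solar noon (hour angle zero) on ``date``'s day."""
    _validate_coords(latitude, longitude)
    t = _to_utc(date).replace(hour=12, minute=0, second=0, microsecond=0)
    _, eqtime = _sun_angles(_julian_centuries(t))
    minutes = 720.0 - 4.0 * longitude - eqtime
    base = t.replace(hour=0)
    return base + timedelta(minutes=minutes % 1440.0)
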