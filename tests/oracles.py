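"""Independent test oracles.

Solar position after Meeus, *Astronomical Algorithms* ch. 25 (low-accuracy
sun): geometric mean longitude/anomaly, equation of centre, apparent
longitude with nutation/aberration, obliquity, equatorial coordinates, and
sidereal-time hour angle.  This is a different formulation from the
NOAA fractional-year series used by the package, so agreement between the
two is a meaningful cross-check, not a tautology.
"""

from __future__ import annotations

import math
from datetime import datetime, timezone


def _julian_day(t: datetime) -> float:
    t = t.astimezone(timezone.utc)
    frac = (t.hour * 3600 + t.minute * 60 + t.second + t.microsecond / 1e6) / 86400.0
    return t.toordinal() + 1721424.5 + frac


def sun_zenith_meeus(latitude: float, longitude: float, t: datetime) -> float:
    """Geometric solar zenith angle in degrees (no refraction)."""
    jd = _julian_day(t)
    T = (jd - 2451545.0) / 36525.0
    rad = math.radians

    L0 = (280.46646 + 36000.76983 * T + 0.0003032 * T * T) % 360.0
    M = 357.52911 + 35999.05029 * T - 0.0001537 * T * T
    C = (
        (1.914602 - 0.004817 * T - 0.000014 * T * T) * math.sin(rad(M))
        + (0.019993 - 0.000101 * T) * math.sin(rad(2 * M))
        + 0.000289 * math.sin(rad(3 * M))
    )
    true_long = L0 + C
    omega = 125.04 - 1934.136 * T
    lam = true_long - 0.00569 - 0.00478 * math.sin(rad(omega))

    eps0 = (
        23.0 + 26.0 / 60.0 + 21.448 / 3600.0
        - (46.815 * T + 0.00059 * T * T - 0.001813 * T**3) / 3600.0
    )
    eps = eps0 + 0.00256 * math.cos(rad(omega))

    sin_lam = math.sin(rad(lam))
    ra = math.degrees(math.atan2(math.cos(rad(eps)) * sin_lam, math.cos(rad(lam))))
    dec = math.degrees(math.asin(math.sin(rad(eps)) * sin_lam))

    gmst = (
        280.46061837
        + 360.98564736629 * (jd - 2451545.0)
        + 0.000387933 * T * T
        - T**3 / 38710000.0
    ) % 360.0
    ha = rad((gmst + longitude - ra) % 360.0)

    phi = rad(latitude)
    cos_zen = math.sin(phi) * math.sin(rad(dec)) + math.cos(phi) * math.cos(rad(dec)) * math.cos(ha)
    return math.degrees(math.acos(max(-1.0, min(1.0, cos_zen))))
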