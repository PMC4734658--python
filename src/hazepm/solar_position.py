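"""Solar geometry: declination, hour angle and zenith angle.

The zenith angle follows the spherical-astronomy identity

    cos(theta_s) = sin(phi) sin(delta) + cos(phi) cos(delta) cos(h)

with phi the observer latitude, delta the solar declination and h the local
hour angle.  Declination and the equation of time come from Spencer's
truncated Fourier series in the day angle, which is accurate to a few
hundredths of a degree in delta and a fraction of a minute in the equation
of time — ample for a regression covariate, and verified in the test suite
to agree with an independent high-precision ephemeris to well under half a
degree in zenith.  Altitude is accepted by callers but plays no role: the
zenith identity has no altitude term and no refraction correction is
applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timezone


@dataclass(frozen=True)
class SolarGeometry:
    """Solar declination, local hour angle and zenith angle, all in degrees."""

    declination: float
    hour_angle: float
    zenith: float


def zenith_from_components(latitude: float, declination: float, hour_angle: float) -> float:
    """Zenith angle (degrees) from latitude, declination and hour angle.

    The cosine argument is clamped to [-1, 1] to absorb rounding at the
    poles/zenith.
    """
    phi = math.radians(latitude)
    delta = math.radians(declination)
    h = math.radians(hour_angle)
    cos_z = math.sin(phi) * math.sin(delta) + math.cos(phi) * math.cos(delta) * math.cos(h)
    return math.degrees(math.acos(max(-1.0, min(1.0, cos_z))))


def _day_angle(timestamp_utc: datetime) -> float:
    """Day angle in radians: 2*pi*(day_of_year - 1 + fractional day)/365."""
    doy = timestamp_utc.timetuple().tm_yday
    frac = (
        timestamp_utc.hour + timestamp_utc.minute / 60.0 + timestamp_utc.second / 3600.0
    ) / 24.0
    return 2.0 * math.pi * (doy - 1 + frac) / 365.0


def declination_deg(timestamp_utc: datetime) -> float:
    """Solar declination (degrees) from Spencer's Fourier series."""
    g = _day_angle(timestamp_utc)
    delta = (
        0.006918
        - 0.399912 * math.cos(g)
        + 0.070257 * math.sin(g)
        - 0.006758 * math.cos(2 * g)
        + 0.000907 * math.sin(2 * g)
        - 0.002697 * math.cos(3 * g)
        + 0.001480 * math.sin(3 * g)
    )
    return math.degrees(delta)


def equation_of_time_minutes(timestamp_utc: datetime) -> float:
    """Equation of time (minutes): apparent minus mean solar time."""
    g = _day_angle(timestamp_utc)
    return 229.18 * (
        0.000075
        + 0.001868 * math.cos(g)
        - 0.032077 * math.sin(g)
        - 0.014615 * math.cos(2 * g)
        - 0.040849 * math.sin(2 * g)
    )


def solar_geometry(timestamp_utc: datetime, longitude: float, latitude: float) -> SolarGeometry:
    """Solar declination, hour angle and zenith for a time and place.

    ``timestamp_utc`` must be timezone-aware (converted to UTC internally);
    longitude is degrees east, latitude degrees north.  Supported years:
    1950-2050 (the ephemeris series degrades outside that window).
    """
    if not -180.0 <= longitude <= 180.0:
        raise ValueError(f"longitude {longitude} outside [-180, 180]")
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude {latitude} outside [-90, 90]")
    if timestamp_utc.tzinfo is None:
        raise ValueError("timestamp must be timezone-aware")
    ts = timestamp_utc.astimezone(timezone.utc)
    if not 1950 <= ts.year <= 2050:
        raise ValueError(f"year {ts.year} outside supported range 1950-2050")

    delta = declination_deg(ts)
    eot = equation_of_time_minutes(ts)
    utc_hours = ts.hour + ts.minute / 60.0 + ts.second / 3600.0 + ts.microsecond / 3.6e9
    # Apparent solar time in hours; 15 degrees of longitude per hour.
    ast = utc_hours + longitude / 15.0 + eot / 60.0
    hour_angle = ((ast - 12.0) * 15.0 + 180.0) % 360.0 - 180.0
    zen = zenith_from_components(latitude, delta, hour_angle)
    return SolarGeometry(declination=delta, hour_angle=hour_angle, zenith=zen)
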