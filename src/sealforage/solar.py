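"""Solar position from first principles (NOAA solar-calculator equations).

Geometric (unrefracted) solar elevation, accurate to well under 0.1 degree
for the years around 2000-2100, which is ample for day/twilight/night
classification of dives.
"""

from __future__ import annotations

from datetime import datetime, timezone

import numpy as np

__all__ = ["solar_elevation", "to_epoch_seconds"]


def to_epoch_seconds(t) -> np.ndarray:
    """Convert datetimes (datetime, ISO string, numpy datetime64, or epoch
    seconds) to float seconds since the Unix epoch, UTC."""
    if isinstance(t, datetime):
        if t.tzinfo is None:
            t = t.replace(tzinfo=timezone.utc)
        return np.asarray(t.timestamp(), dtype=float)
    arr = np.asarray(t)
    if np.issubdtype(arr.dtype, np.datetime64):
        return arr.astype("datetime64[ns]").astype("int64") / 1e9
    if arr.dtype.kind in "US":
        return arr.astype("datetime64[ns]").astype("int64") / 1e9
    return arr.astype(float)


def solar_elevation(lat: float, lon: float, t) -> np.ndarray:
    """Geometric solar elevation angle in degrees.

    Parameters
    ----------
    lat, lon
        Latitude (positive north) and longitude (positive east), degrees.
    t
        Time(s), UTC: epoch seconds, datetime, or datetime64 (scalar/array).

    Returns
    -------
    Elevation above the horizon in degrees (scalar if ``t`` is scalar).
    """
    if not np.all(np.abs(lat) <= 90):
        raise ValueError("latitude must be within [-90, 90] degrees")
    if not np.all(np.abs(lon) <= 360):
        raise ValueError("longitude out of range")

    epoch = to_epoch_seconds(t)
    scalar = np.ndim(epoch) == 0
    epoch = np.atleast_1d(epoch).astype(float)

    jd = epoch / 86400.0 + 2440587.5
    T = (jd - 2451545.0) / 36525.0  # Julian centuries since J2000

    rad = np.deg2rad
    l0 = np.mod(280.46646 + T * (36000.76983 + 0.0003032 * T), 360.0)
    m = 357.52911 + T * (35999.05029 - 0.0001537 * T)
    ecc = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)
    c = (
        np.sin(rad(m)) * (1.914602 - T * (0.004817 + 0.000014 * T))
        + np.sin(rad(2 * m)) * (0.019993 - 0.000101 * T)
        + np.sin(rad(3 * m)) * 0.000289
    )
    true_long = l0 + c
    omega = 125.04 - 1934.136 * T
    app_long = true_long - 0.00569 - 0.00478 * np.sin(rad(omega))

    e0 = 23.0 + (26.0 + (21.448 - T * (46.815 + T * (0.00059 - T * 0.001813))) / 60.0) / 60.0
    eps = e0 + 0.00256 * np.cos(rad(omega))

    decl = np.arcsin(np.sin(rad(eps)) * np.sin(rad(app_long)))

    y = np.tan(rad(eps / 2.0)) ** 2
    eqtime = 4.0 * np.rad2deg(
        y * np.sin(2 * rad(l0))
        - 2.0 * ecc * np.sin(rad(m))
        + 4.0 * ecc * y * np.sin(rad(m)) * np.cos(2 * rad(l0))
        - 0.5 * y * y * np.sin(4 * rad(l0))
        - 1.25 * ecc * ecc * np.sin(2 * rad(m))
    )  # minutes

    minutes_utc = np.mod(epoch, 86400.0) / 60.0
    tst = np.mod(minutes_utc + eqtime + 4.0 * lon, 1440.0)
    ha = tst / 4.0 - 180.0  # degrees

    phi = rad(lat)
    cos_zen = np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.cos(rad(ha))
    cos_zen = np.clip(cos_zen, -1.0, 1.0)
    elev = 90.0 - np.rad2deg(np.arccos(cos_zen))
    return float(elev[0]) if scalar else elev
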