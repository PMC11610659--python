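"""Solar geometry for day/night classification.

Day and night are split at solar elevation 0 (geometric sunrise/sunset,
no twilight band) computed from a fixed site location.  The default site
sits at 55.75 N, 6.25 W — a west-of-Scotland latitude where mid-winter
days are short (~7 h) and late-April days long (~15 h), which is the
seasonal range the activity-budget models care about.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SITE_LAT = 55.75
SITE_LON = -6.25


def solar_elevation(timestamps, lat: float = SITE_LAT, lon: float = SITE_LON) -> np.ndarray:
    """Solar elevation angle (degrees) at UTC ``timestamps``.

    Standard low-precision ephemeris: solar declination from day of year,
    hour angle from UTC clock time corrected for longitude and the
    equation of time.  Accuracy ~0.5 degrees, ample for a day/night split.
    """
    ts = pd.DatetimeIndex(timestamps)
    doy = ts.dayofyear.to_numpy()
    frac_hour = (
        ts.hour.to_numpy()
        + ts.minute.to_numpy() / 60.0
        + ts.second.to_numpy() / 3600.0
    )
    gamma = 2.0 * np.pi / 365.0 * (doy - 1 + (frac_hour - 12.0) / 24.0)
    # Equation of time (minutes) and declination (radians), Spencer series.
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )
    time_offset = eqtime + 4.0 * lon
    tst = frac_hour * 60.0 + time_offset
    ha = np.deg2rad(tst / 4.0 - 180.0)
    lat_r = np.deg2rad(lat)
    cos_zen = np.sin(lat_r) * np.sin(decl) + np.cos(lat_r) * np.cos(decl) * np.cos(ha)
    return np.rad2deg(np.arcsin(np.clip(cos_zen, -1.0, 1.0)))


def is_daytime(timestamps, lat: float = SITE_LAT, lon: float = SITE_LON) -> np.ndarray:
    """Boolean array: sun above the horizon at each UTC timestamp."""
    return solar_elevation(timestamps, lat=lat, lon=lon) > 0.0


def daylight_window(date, lat: float = SITE_LAT, lon: float = SITE_LON):
    """(sunrise, sunset) UTC timestamps for a calendar date, by bisection.

    Searches minute resolution over the 24 h of ``date``; assumes the sun
    rises and sets exactly once (true at temperate latitudes).
    """
    day = pd.Timestamp(date).normalize()
    minutes = pd.date_range(day, day + pd.Timedelta(hours=24), freq="1min", inclusive="left")
    up = is_daytime(minutes, lat=lat, lon=lon)
    if not up.any():
        raise ValueError(f"sun never rises on {day.date()} at lat {lat}")
    idx = np.nonzero(up)[0]
    return minutes[idx[0]], minutes[idx[-1]]
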