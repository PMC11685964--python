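"""Self-contained solar and lunar ephemeris.

Low-precision analytic series (truncated Meeus-style polynomials for the
Sun, the Astronomical Almanac low-precision series for the Moon).  Accuracy
is ~0.01 deg for solar position and ~0.3 deg for lunar position — far below
the error of threshold light-level geolocation, which is what these
quantities feed.  All angles are degrees, all times UTC.

Conventions
-----------
* Longitude east-positive in [-180, 180].
* ``sun_elev='horizon'`` applies the standard -0.833 deg refraction +
  semidiameter adjustment; any numeric elevation (e.g. the -4.5 deg
  geolocation threshold) is used as-is.
* Supported epoch 1990-2050 (enforced for the lunar phase functions).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as _date, datetime, timedelta, timezone

import numpy as np

__all__ = [
    "SolarEvent",
    "MoonState",
    "sun_altitude",
    "sun_declination",
    "equation_of_time",
    "day_length",
    "sun_events",
    "moon_illumination",
    "moon_altitude",
    "moon_windows",
    "moon_table",
]

HORIZON_ELEV = -0.8333  # refraction + solar semidiameter, degrees

_J2000 = 2451545.0
_DEG = np.pi / 180.0


@dataclass(frozen=True)
class SolarEvent:
    """A sunrise or sunset at a stated reference sun elevation."""

    date: _date
    event: str  # 'sunrise' | 'sunset'
    time: datetime
    sun_elev: float


@dataclass(frozen=True)
class MoonState:
    """Moon conditions for one (10-min) night bin."""

    time: datetime
    illuminated_fraction: float
    risen: bool
    rise_time: datetime | None
    set_time: datetime | None


# ---------------------------------------------------------------------------
# time scaffolding


def _to_dt64(t):
    """Coerce datetime / datetime64 / iterables thereof to datetime64[s],
    treating tz-aware datetimes as UTC."""
    if isinstance(t, datetime):
        if t.tzinfo is not None:
            t = t.astimezone(timezone.utc).replace(tzinfo=None)
        return np.datetime64(t, "s")
    if isinstance(t, (list, tuple)) and t and isinstance(t[0], datetime):
        return np.array([_to_dt64(x) for x in t])
    return np.asarray(t, dtype="datetime64[s]")


def julian_day(t) -> np.ndarray | float:
    """UTC instant(s) -> Julian day number. Accepts datetime, numpy
    datetime64, or arrays thereof."""
    arr = _to_dt64(t)
    jd = arr.astype("int64") / 86400.0 + 2440587.5
    return jd if arr.ndim else float(jd)


def _centuries(jd):
    return (np.asarray(jd) - _J2000) / 36525.0


def _wrap360(x):
    return np.mod(x, 360.0)


def wrap_lon(lon):
    """Wrap longitude into [-180, 180)."""
    return np.mod(np.asarray(lon) + 180.0, 360.0) - 180.0


# ---------------------------------------------------------------------------
# solar position


def _solar_coords(jd):
    """Return (apparent ecliptic longitude, obliquity, RA, dec, eq. of time
    in minutes), all degrees except EoT."""
    T = _centuries(jd)
    L0 = _wrap360(280.46646 + 36000.76983 * T + 0.0003032 * T * T)
    M = _wrap360(357.52911 + 35999.05029 * T - 0.0001537 * T * T)
    Mr = M * _DEG
    C = (
        (1.914602 - 0.004817 * T - 0.000014 * T * T) * np.sin(Mr)
        + (0.019993 - 0.000101 * T) * np.sin(2 * Mr)
        + 0.000289 * np.sin(3 * Mr)
    )
    true_lon = L0 + C
    omega = (125.04 - 1934.136 * T) * _DEG
    lam = true_lon - 0.00569 - 0.00478 * np.sin(omega)  # apparent
    eps = 23.4392911 - 0.0130042 * T + 0.00256 * np.cos(omega)
    lam_r, eps_r = lam * _DEG, eps * _DEG
    ra = np.arctan2(np.cos(eps_r) * np.sin(lam_r), np.cos(lam_r)) / _DEG
    dec = np.arcsin(np.sin(eps_r) * np.sin(lam_r)) / _DEG
    # equation of time, minutes (Meeus 28.3 rearranged)
    eot = 4.0 * (_wrap360(L0 - 0.0057183 - ra + 180.0) - 180.0)
    return lam, eps, _wrap360(ra), dec, eot


def sun_declination(t):
    """Solar declination (deg) at UTC instant(s)."""
    return _solar_coords(julian_day(t))[3]


def equation_of_time(t):
    """Apparent minus mean solar time, in minutes, at UTC instant(s)."""
    return _solar_coords(julian_day(t))[4]


def _gmst(jd):
    d = np.asarray(jd) - _J2000
    T = d / 36525.0
    return _wrap360(280.46061837 + 360.98564736629 * d + 0.000387933 * T * T)


def sun_altitude(t, lon, lat):
    """Geocentric solar altitude (deg) at UTC instant(s) and position."""
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude out of range [-90, 90]")
    jd = julian_day(t)
    _, _, ra, dec, _ = _solar_coords(jd)
    H = (_gmst(jd) + np.asarray(lon, dtype=float) - ra) * _DEG
    phi, d = lat * _DEG, dec * _DEG
    alt = np.arcsin(
        np.sin(phi) * np.sin(d) + np.cos(phi) * np.cos(d) * np.cos(H)
    ) / _DEG
    return alt if np.ndim(alt) else float(alt)


def _resolve_elev(sun_elev):
    if isinstance(sun_elev, str):
        if sun_elev != "horizon":
            raise ValueError(f"unknown sun_elev keyword {sun_elev!r}")
        return HORIZON_ELEV
    return float(sun_elev)


def day_length(date, lat, sun_elev=0.0):
    """Hours of sun above ``sun_elev`` on ``date`` at latitude ``lat``.

    Returns 0.0 for polar night and 24.0 for polar day rather than raising.
    """
    lat = float(lat)
    if abs(lat) > 90.0:
        raise ValueError("latitude out of range [-90, 90]")
    elev = _resolve_elev(sun_elev)
    noon = datetime(date.year, date.month, date.day, 12, tzinfo=timezone.utc)
    dec = sun_declination(noon)
    cosH = (np.sin(elev * _DEG) - np.sin(lat * _DEG) * np.sin(dec * _DEG)) / (
        np.cos(lat * _DEG) * np.cos(dec * _DEG)
    )
    if cosH >= 1.0:
        return 0.0
    if cosH <= -1.0:
        return 24.0
    return float(2.0 * np.arccos(cosH) / _DEG / 15.0)


def _solar_noon_utc(date, lon):
    """UTC datetime of local apparent noon (one fixed-point refinement)."""
    approx = datetime(date.year, date.month, date.day, 12, tzinfo=timezone.utc)
    t = approx
    for _ in range(2):
        eot_h = equation_of_time(t) / 60.0
        hours = 12.0 - eot_h - lon / 15.0
        t = datetime(date.year, date.month, date.day, tzinfo=timezone.utc) + timedelta(
            hours=float(hours)
        )
    return t


def sun_events(date, lon, lat, sun_elev=0.0):
    """(sunrise, sunset) SolarEvents for ``date`` at (lon, lat), or
    (None, None) for polar day/night at the requested elevation."""
    elev = _resolve_elev(sun_elev)
    noon = _solar_noon_utc(date, lon)
    half = day_length(date, lat, elev) / 2.0
    if half <= 0.0 or half >= 12.0:
        return None, None
    rise_t, set_t = noon - timedelta(hours=half), noon + timedelta(hours=half)
    # one refinement with declination at the event itself
    for _ in range(2):
        half_r = _half_day(rise_t, lat, elev)
        half_s = _half_day(set_t, lat, elev)
        if half_r is None or half_s is None:
            break
        rise_t = noon - timedelta(hours=half_r)
        set_t = noon + timedelta(hours=half_s)
    return (
        SolarEvent(date, "sunrise", rise_t, elev),
        SolarEvent(date, "sunset", set_t, elev),
    )


def _half_day(t, lat, elev):
    dec = sun_declination(t)
    cosH = (np.sin(elev * _DEG) - np.sin(lat * _DEG) * np.sin(dec * _DEG)) / (
        np.cos(lat * _DEG) * np.cos(dec * _DEG)
    )
    if abs(cosH) >= 1.0:
        return None
    return float(np.arccos(cosH) / _DEG / 15.0)


# ---------------------------------------------------------------------------
# lunar position and phase

_EPOCH_LO = datetime(1990, 1, 1, tzinfo=timezone.utc)
_EPOCH_HI = datetime(2050, 12, 31, tzinfo=timezone.utc)


def _check_epoch(t):
    arr = _to_dt64(t)
    lo = np.datetime64(_EPOCH_LO.replace(tzinfo=None))
    hi = np.datetime64(_EPOCH_HI.replace(tzinfo=None))
    if np.any(arr < lo) or np.any(arr > hi):
        raise ValueError("time outside supported ephemeris epoch 1990-2050")


def _lunar_coords(jd):
    """Astronomical Almanac low-precision lunar series.

    Returns (ecliptic lon deg, ecliptic lat deg, horizontal parallax deg).
    Accuracy ~0.3 deg in longitude, ~0.2 deg in latitude.
    """
    T = _centuries(jd)

    def s(a, b):
        return np.sin((a + b * T) * _DEG)

    def c(a, b):
        return np.cos((a + b * T) * _DEG)

    lam = (
        218.32
        + 481267.881 * T
        + 6.29 * s(135.0, 477198.87)
        - 1.27 * s(259.3, -413335.36)
        + 0.66 * s(235.7, 890534.22)
        + 0.21 * s(269.9, 954397.74)
        - 0.19 * s(357.5, 35999.05)
        - 0.11 * s(186.5, 966404.03)
    )
    beta = (
        5.13 * s(93.3, 483202.02)
        + 0.28 * s(228.2, 960400.89)
        - 0.28 * s(318.3, 6003.15)
        - 0.17 * s(217.6, -407332.21)
    )
    par = (
        0.9508
        + 0.0518 * c(135.0, 477198.87)
        + 0.0095 * c(259.3, -413335.36)
        + 0.0078 * c(235.7, 890534.22)
        + 0.0028 * c(269.9, 954397.74)
    )
    return _wrap360(lam), beta, par


def moon_illumination(t):
    """Illuminated fraction of the lunar disc (0 new .. 1 full) at UTC
    instant(s); |error| <= 0.02 vs published ephemerides."""
    _check_epoch(t)
    jd = julian_day(t)
    lam_s, _, _, _, _ = _solar_coords(jd)
    lam_m, beta_m, par = _lunar_coords(jd)
    # geocentric elongation
    psi = np.arccos(
        np.clip(
            np.cos(beta_m * _DEG) * np.cos((lam_m - lam_s) * _DEG), -1.0, 1.0
        )
    )
    # phase angle with finite sun distance (Meeus 48.2); distances in
    # earth radii: moon from parallax, sun ~23455 ER
    delta = 1.0 / np.sin(par * _DEG)
    i = np.arctan2(23455.0 * np.sin(psi), delta - 23455.0 * np.cos(psi))
    k = (1.0 + np.cos(i)) / 2.0
    return k if np.ndim(k) else float(k)


def moon_altitude(t, lon, lat):
    """Topocentric lunar altitude (deg): geocentric altitude with the
    first-order parallax correction."""
    jd = julian_day(t)
    lam, beta, par = _lunar_coords(jd)
    T = _centuries(jd)
    eps = (23.4392911 - 0.0130042 * T) * _DEG
    lam_r, beta_r = lam * _DEG, beta * _DEG
    ra = np.arctan2(
        np.sin(lam_r) * np.cos(eps) - np.tan(beta_r) * np.sin(eps),
        np.cos(lam_r),
    ) / _DEG
    dec = np.arcsin(
        np.sin(beta_r) * np.cos(eps) + np.cos(beta_r) * np.sin(eps) * np.sin(lam_r)
    ) / _DEG
    H = (_gmst(jd) + np.asarray(lon, dtype=float) - ra) * _DEG
    phi, d = np.asarray(lat, dtype=float) * _DEG, dec * _DEG
    alt = np.arcsin(
        np.sin(phi) * np.sin(d) + np.cos(phi) * np.cos(d) * np.cos(H)
    ) / _DEG
    alt = alt - par * np.cos(alt * _DEG)  # topocentric correction
    return alt if np.ndim(alt) else float(alt)


# standard altitude of the moon's upper limb at rise/set: 0.7275*parallax
# minus 34' refraction; using the mean parallax this is ~ +0.125 deg
_MOON_RISE_ALT = 0.125


def _moon_crossings(t0, t1, lon, lat, step_minutes=2):
    """(rise_times, set_times) of the moon between t0 and t1, by scanning
    topocentric altitude and linearly refining each sign change."""
    n = int((t1 - t0).total_seconds() // (step_minutes * 60)) + 1
    times = np.datetime64(t0.replace(tzinfo=None), "s") + np.arange(n) * np.timedelta64(
        step_minutes * 60, "s"
    )
    alt = np.asarray(moon_altitude(times, lon, lat)) - _MOON_RISE_ALT
    rises, sets = [], []
    sign = alt > 0
    idx = np.nonzero(sign[1:] != sign[:-1])[0]
    for i in idx:
        f = alt[i] / (alt[i] - alt[i + 1])
        tc = times[i] + np.timedelta64(int(f * step_minutes * 60), "s")
        tc = datetime.fromtimestamp(tc.astype("int64"), tz=timezone.utc)
        (rises if not sign[i] else sets).append(tc)
    return rises, sets


def moon_windows(date, lon, lat, bin_minutes=10):
    """MoonState sequence for the night following ``date`` (local sunset to
    next sunrise), one state per ``bin_minutes`` bin."""
    if not (np.isfinite(lon) and np.isfinite(lat)):
        raise ValueError("position must be finite")
    rise_ev, set_ev = sun_events(date, lon, lat, "horizon")
    if set_ev is None:
        # polar day/night: use local solar midnight +/- 6 h as "night"
        noon = _solar_noon_utc(date, lon)
        night_start = noon + timedelta(hours=6)
        night_end = noon + timedelta(hours=18)
    else:
        night_start = set_ev.time
        nr, _ = sun_events(date + timedelta(days=1), lon, lat, "horizon")
        night_end = nr.time if nr is not None else set_ev.time + timedelta(hours=12)
    rises, sets = _moon_crossings(
        night_start - timedelta(hours=1), night_end + timedelta(hours=1), lon, lat
    )
    rise_t = rises[0] if rises else None
    set_t = sets[0] if sets else None
    states = []
    t = night_start
    while t < night_end:
        states.append(
            MoonState(
                time=t,
                illuminated_fraction=moon_illumination(t),
                risen=bool(moon_altitude(t, lon, lat) > _MOON_RISE_ALT),
                rise_time=rise_t,
                set_time=set_t,
            )
        )
        t = t + timedelta(minutes=bin_minutes)
    return states


def night_illumination(date, lon):
    """Illuminated fraction at local solar midnight following ``date`` —
    the single per-night moon covariate used by the models."""
    noon = _solar_noon_utc(date, lon)
    return moon_illumination(noon + timedelta(hours=12))


def moon_table(start, end, lon, lat):
    """Per-night moon summary rows from ``start`` to ``end`` (dates):
    (date, illumination at local solar midnight, moon-up fraction of night)."""
    import pandas as pd

    rows = []
    d = start
    while d <= end:
        states = moon_windows(d, lon, lat)
        up = float(np.mean([s.risen for s in states])) if states else np.nan
        rows.append(
            {
                "date": d,
                "moon_illumination": night_illumination(d, lon),
                "moon_up_fraction": up,
            }
        )
        d = d + timedelta(days=1)
    return pd.DataFrame(rows)
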