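"""Threshold-method light-level geolocation and migration phenology.

Twilights are detected as interpolated threshold crossings of the light
curve; longitude comes from the timing of local apparent noon/midnight
(corrected by the equation of time, 15 deg per hour), latitude from
inverting day length at the calibrated sun elevation angle.  Latitude is
unidentifiable near the equinoxes (day length is ~12 h everywhere) and is
masked there; longitude is not affected, which is why phenology is read
from the smoothed longitude series.

Migration start/end is an automated rule standing in for the visual
inspection of longitudinal change: start at the first run of sustained
westward movement, end when the smoothed longitude settles inside the
wintering longitude band.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import astro
from .astro import SolarEvent
from .synth import LightSeries

__all__ = [
    "GeolocationConfig",
    "PositionTrack",
    "detect_twilights",
    "estimate_position",
    "build_track",
    "calibrate_sun_elevation",
    "detect_migration_window",
]

_DEG = np.pi / 180.0

# autumn equinox dates (approx.; latitude masking window is +/- 15 d)
_EQUINOXES = ((3, 20), (9, 22))


@dataclass(frozen=True)
class GeolocationConfig:
    light_threshold: float = 32.0
    sun_elev: float = -4.5
    smoothing_window: int = 3  # days, odd
    equinox_halfwidth: int = 15  # days
    min_dark_hours: float = 4.0  # shorter dark/light spells = shading artifacts
    min_daily_lon_change: float = 0.5  # deg/day westward, start rule
    start_lag_days: int = 2  # centred smoothing + midday positions make the
    # first qualifying change precede the true departure; calibrated offset
    persistence_days: int = 5
    end_persistence_days: int = 3
    end_lag_days: int = 3  # the band-entry rule fires when the bird crosses
    # into the wintering longitude band, ~3 days before it reaches the box
    # centre; calibrated offset so detected durations are unbiased
    wintering_lon_band: tuple[float, float] = (-66.0, -54.0)

    def __post_init__(self):
        if self.smoothing_window % 2 != 1 or self.smoothing_window < 1:
            raise ValueError("smoothing_window must be odd and >= 1")
        if self.persistence_days < 1 or self.end_persistence_days < 1:
            raise ValueError("persistence days must be >= 1")


@dataclass
class PositionTrack:
    """Bi-daily position estimates plus derived phenology for one bird."""

    bird_id: str
    positions: pd.DataFrame  # date, half, lon, lat, equinox_flag
    daily_lon: pd.Series  # per-date mean longitude
    smoothed_lon: pd.Series  # rolling-mean longitude
    migration_start: dt.date | None = None
    migration_end: dt.date | None = None
    incomplete: bool = False

    @property
    def duration_days(self) -> int | None:
        if self.migration_start is None or self.migration_end is None:
            return None
        return (self.migration_end - self.migration_start).days

    def to_frame(self) -> pd.DataFrame:
        out = self.positions.copy()
        out.insert(0, "bird_id", self.bird_id)
        return out


# ---------------------------------------------------------------------------
# twilight detection


def detect_twilights(light: LightSeries, cfg: GeolocationConfig) -> list[SolarEvent]:
    """Alternating sunrise/sunset events at interpolated threshold
    crossings.  Dark or light spells shorter than ``min_dark_hours`` are
    treated as shading artifacts (or noise spikes) and merged away.
    Days with constant light produce no events (flagged, not errored).
    """
    t = light.times.astype("datetime64[s]")
    if len(t) < 2:
        raise ValueError("need at least 24 h of light data")
    step_s = float((t[1] - t[0]) / np.timedelta64(1, "s"))
    if (t[-1] - t[0]) < np.timedelta64(24 * 3600 - 1, "s"):
        raise ValueError("need at least 24 h of light data")
    y = light.light - cfg.light_threshold
    above = y > 0

    idx = np.nonzero(above[1:] != above[:-1])[0]
    events = []  # (time_seconds_since_t0, kind) kind: +1 sunrise, -1 sunset
    t0 = t[0]
    for i in idx:
        f = y[i] / (y[i] - y[i + 1])
        secs = (t[i] - t0) / np.timedelta64(1, "s") + f * step_s
        events.append([float(secs), 1 if not above[i] else -1])

    min_s = cfg.min_dark_hours * 3600.0
    # iteratively delete short dark (sunset->sunrise) and short light
    # (sunrise->sunset) intervals
    changed = True
    while changed and len(events) >= 2:
        changed = False
        for i in range(len(events) - 1):
            a, b = events[i], events[i + 1]
            if b[0] - a[0] < min_s:
                del events[i : i + 2]
                changed = True
                break

    out = []
    for secs, kind in events:
        when = t0 + np.timedelta64(int(round(secs)), "s")
        py = pd.Timestamp(when).to_pydatetime().replace(tzinfo=dt.timezone.utc)
        out.append(
            SolarEvent(
                date=py.date(),
                event="sunrise" if kind == 1 else "sunset",
                time=py,
                sun_elev=cfg.sun_elev,
            )
        )
    return out


# ---------------------------------------------------------------------------
# position estimation


def _invert_day_length(hours: float, dec_deg: float, sun_elev: float):
    """Latitude whose day length at declination `dec` equals `hours`.

    Solves sin(e) = sin(lat) sin(dec) + cos(lat) cos(dec) cos(H0) for lat,
    H0 = hours/2 * 15 deg.  Returns None when no root exists.
    """
    H0 = hours / 2.0 * 15.0 * _DEG
    A = np.sin(dec_deg * _DEG)
    B = np.cos(H0) * np.cos(dec_deg * _DEG)
    R = np.hypot(A, B)
    s = np.sin(sun_elev * _DEG) / R
    if abs(s) > 1.0:
        return None
    theta = np.arctan2(B, A)
    for lat in (np.arcsin(s) - theta, np.pi - np.arcsin(s) - theta):
        lat_deg = np.degrees(
            np.arctan2(np.sin(lat), np.cos(lat))
        )
        if -90.0 <= lat_deg <= 90.0:
            # verify (two-branch solve can return the spurious branch)
            chk = np.sin(lat * 1.0)
            lhs = A * np.sin(lat) + B * np.cos(lat)
            if abs(lhs - np.sin(sun_elev * _DEG)) < 1e-9:
                return float(lat_deg)
    return None


def _near_equinox(date: dt.date, halfwidth: int) -> bool:
    for m, d in _EQUINOXES:
        eq = dt.date(date.year, m, d)
        if abs((date - eq).days) <= halfwidth:
            return True
    return False


def estimate_position(sunrise: dt.datetime, sunset: dt.datetime, date: dt.date,
                      sun_elev: float = -4.5, equinox_halfwidth: int = 15):
    """(lon, lat-or-None, equinox_flag) from one twilight pair.

    Works for both halves of the bi-daily scheme: pass (sunrise, sunset)
    for the midday position or (sunset, next sunrise) in either order —
    the earlier time must come first; a "night" pair is recognised when the
    first event is a sunset, i.e. the midpoint is local apparent midnight.
    """
    if sunrise >= sunset:
        raise ValueError("first twilight must precede the second")
    mid = sunrise + (sunset - sunrise) / 2
    eot_h = astro.equation_of_time(mid) / 60.0
    utc_h = (
        mid.hour + mid.minute / 60.0 + mid.second / 3600.0 + mid.microsecond / 3.6e9
    )
    lon = astro.wrap_lon(15.0 * (12.0 - eot_h - utc_h))
    hours = (sunset - sunrise).total_seconds() / 3600.0
    equinox = _near_equinox(date, equinox_halfwidth)
    lat = None
    if not equinox:
        dec = astro.sun_declination(mid)
        lat = _invert_day_length(hours, dec, sun_elev)
    return float(lon), lat, equinox


def _night_position(sunset: dt.datetime, sunrise: dt.datetime, date: dt.date,
                    sun_elev: float, equinox_halfwidth: int):
    """Position from a sunset -> next-sunrise pair (midpoint = local
    apparent midnight)."""
    if sunset >= sunrise:
        raise ValueError("sunset must precede the following sunrise")
    mid = sunset + (sunrise - sunset) / 2
    eot_h = astro.equation_of_time(mid) / 60.0
    utc_h = mid.hour + mid.minute / 60.0 + mid.second / 3600.0
    lon = astro.wrap_lon(15.0 * (24.0 - eot_h - utc_h))
    night_hours = (sunrise - sunset).total_seconds() / 3600.0
    equinox = _near_equinox(date, equinox_halfwidth)
    lat = None
    if not equinox:
        dec = astro.sun_declination(mid)
        lat = _invert_day_length(24.0 - night_hours, dec, sun_elev)
    return float(lon), lat, equinox


def build_track(bird_id: str, twilights: list[SolarEvent],
                cfg: GeolocationConfig) -> PositionTrack:
    """Bi-daily positions (midday + midnight per twilight pair) and the
    smoothed longitude series."""
    rows = []
    for a, b in zip(twilights, twilights[1:]):
        try:
            if a.event == "sunrise" and b.event == "sunset":
                lon, lat, eq = estimate_position(
                    a.time, b.time, a.time.date(), cfg.sun_elev,
                    cfg.equinox_halfwidth,
                )
                half = "day"
            elif a.event == "sunset" and b.event == "sunrise":
                lon, lat, eq = _night_position(
                    a.time, b.time, a.time.date(), cfg.sun_elev,
                    cfg.equinox_halfwidth,
                )
                half = "night"
            else:
                continue
        except ValueError:
            continue
        rows.append(
            {
                "date": a.time.date(),
                "half": half,
                "lon": lon,
                "lat": lat if lat is not None else np.nan,
                "equinox_flag": eq,
                "twilight_start": a.time,
                "twilight_end": b.time,
            }
        )
    positions = pd.DataFrame(rows)
    if positions.empty:
        return PositionTrack(
            bird_id, positions, pd.Series(dtype=float), pd.Series(dtype=float),
            incomplete=True,
        )
    daily = positions.groupby("date")["lon"].mean()
    smoothed = daily.rolling(cfg.smoothing_window, center=True, min_periods=1).mean()
    track = PositionTrack(bird_id, positions, daily, smoothed)
    detect_migration_window(track, cfg)
    return track


# ---------------------------------------------------------------------------
# calibration


def calibrate_sun_elevation(light: LightSeries, colony_lat: float,
                            pre_departure_end: dt.date,
                            candidate_range=np.arange(-6.0, -2.9, 0.1),
                            cfg: GeolocationConfig | None = None) -> float:
    """Sun elevation minimising the median absolute latitude error against
    the colony latitude over the pre-departure period."""
    cfg = cfg or GeolocationConfig()
    tw = detect_twilights(light, cfg)
    tw = [e for e in tw if e.time.date() < pre_departure_end]
    n_days = len({e.time.date() for e in tw})
    if n_days < 14:
        raise ValueError("need >= 14 days of pre-departure twilights")
    pairs = [
        (a, b)
        for a, b in zip(tw, tw[1:])
        if a.event == "sunrise" and b.event == "sunset"
    ]
    best, best_err = None, np.inf
    for elev in np.atleast_1d(candidate_range):
        errs = []
        for a, b in pairs:
            d = a.time.date()
            if _near_equinox(d, cfg.equinox_halfwidth):
                continue
            hours = (b.time - a.time).total_seconds() / 3600.0
            mid = a.time + (b.time - a.time) / 2
            lat = _invert_day_length(hours, astro.sun_declination(mid), float(elev))
            if lat is not None:
                errs.append(abs(lat - colony_lat))
        if errs:
            err = float(np.median(errs))
            if err < best_err:
                best, best_err = float(elev), err
    if best is None:
        raise ValueError("no candidate elevation yields finite latitudes")
    return round(best, 6)


# ---------------------------------------------------------------------------
# phenology


def detect_migration_window(track: PositionTrack,
                            cfg: GeolocationConfig) -> tuple:
    """Automated migration start/end from the smoothed longitude series.

    start: first date beginning >= persistence_days consecutive days with
    westward smoothed-longitude change >= min_daily_lon_change.
    end: first date after start with smoothed longitude inside the
    wintering band sustained >= end_persistence_days.
    Only dates from Aug 1 onwards are considered, so prepending earlier
    data cannot change the result.
    """
    s = track.smoothed_lon
    if s.empty:
        track.incomplete = True
        return None, None
    year = s.index[0].year if hasattr(s.index[0], "year") else s.index[0].year
    aug1 = dt.date(year, 8, 1)
    s = s[[d >= aug1 for d in s.index]]
    dates = list(s.index)
    vals = s.to_numpy()
    if len(vals) < cfg.persistence_days + 1:
        track.incomplete = True
        return None, None

    west = -np.diff(vals)  # positive = westward
    qual = west >= cfg.min_daily_lon_change
    start = None
    run = 0
    for i, q in enumerate(qual):
        run = run + 1 if q else 0
        if run >= cfg.persistence_days:
            start = dates[i - run + 1] + dt.timedelta(days=cfg.start_lag_days)
            break

    end = None
    if start is not None:
        lo, hi = cfg.wintering_lon_band
        inband = (vals >= lo) & (vals <= hi)
        run = 0
        for i, d in enumerate(dates):
            if d <= start:
                continue
            run = run + 1 if inband[i] else 0
            if run >= cfg.end_persistence_days:
                end = dates[i - run + 1] + dt.timedelta(days=cfg.end_lag_days)
                break

    track.migration_start = start
    track.migration_end = end
    track.incomplete = start is None or end is None
    return start, end
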