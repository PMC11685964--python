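"""Independent oracles used by the test suite.

These deliberately re-derive quantities through different published
algorithms (or brute force) than the implementation under test:

* a fuller truncated lunar theory (main periodic terms of the modern
  lunar series with fundamental arguments, ~15 longitude and 10 latitude
  terms, accuracy ~0.01 deg) versus the implementation's short
  Almanac-style series;
* moon rise/set by dense 1-minute scanning of the oracle altitude;
* day length by bisection root-finding on the implementation-independent
  solar altitude;
* mixture likelihood by brute-force grid search.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
from scipy import stats

_DEG = np.pi / 180.0
_J2000 = 2451545.0


def _jd(t: dt.datetime) -> float:
    if t.tzinfo is not None:
        t = t.astimezone(dt.timezone.utc).replace(tzinfo=None)
    return (t - dt.datetime(1970, 1, 1)).total_seconds() / 86400.0 + 2440587.5


def moon_ecliptic(t: dt.datetime):
    """(lon, lat) of the moon, degrees, from the main periodic terms of
    the standard lunar theory."""
    T = (_jd(t) - _J2000) / 36525.0
    Lp = 218.3164477 + 481267.88123421 * T - 0.0015786 * T * T
    D = 297.8501921 + 445267.1114034 * T - 0.0018819 * T * T
    M = 357.5291092 + 35999.0502909 * T - 0.0001536 * T * T
    Mp = 134.9633964 + 477198.8675055 * T + 0.0087414 * T * T
    F = 93.2720950 + 483202.0175233 * T - 0.0036539 * T * T
    E = 1.0 - 0.002516 * T - 0.0000074 * T * T

    def s(c, d_, m_, mp_, f_):
        term = c * np.sin((d_ * D + m_ * M + mp_ * Mp + f_ * F) * _DEG)
        return term * (E ** abs(m_))

    lon_terms = (
        s(6288774, 0, 0, 1, 0) + s(1274027, 2, 0, -1, 0) + s(658314, 2, 0, 0, 0)
        + s(213618, 0, 0, 2, 0) + s(-185116, 0, 1, 0, 0) + s(-114332, 0, 0, 0, 2)
        + s(58793, 2, 0, -2, 0) + s(57066, 2, -1, -1, 0) + s(53322, 2, 0, 1, 0)
        + s(45758, 2, -1, 0, 0) + s(-40923, 0, 1, -1, 0) + s(-34720, 1, 0, 0, 0)
        + s(-30383, 0, 1, 1, 0) + s(15327, 2, 0, 0, -2) + s(-12528, 0, 0, 1, 2)
        + s(10980, 0, 0, 1, -2) + s(10675, 4, 0, -1, 0) + s(10034, 0, 0, 3, 0)
    )
    lat_terms = (
        s(5128122, 0, 0, 0, 1) + s(280602, 0, 0, 1, 1) + s(277693, 0, 0, 1, -1)
        + s(173237, 2, 0, 0, -1) + s(55413, 2, 0, -1, 1) + s(46271, 2, 0, -1, -1)
        + s(32573, 2, 0, 0, 1) + s(17198, 0, 0, 2, 1) + s(9266, 2, 0, 1, -1)
        + s(8822, 0, 0, 2, -1)
    )
    lon = (Lp + lon_terms / 1e6) % 360.0
    lat = lat_terms / 1e6
    return lon, lat


def _gmst(jd):
    d = jd - _J2000
    T = d / 36525.0
    return (280.46061837 + 360.98564736629 * d + 0.000387933 * T * T) % 360.0


def moon_altitude(t: dt.datetime, lon: float, lat: float) -> float:
    """Geocentric lunar altitude via the oracle position (no parallax)."""
    jd = _jd(t)
    T = (jd - _J2000) / 36525.0
    lam, beta = moon_ecliptic(t)
    eps = (23.4392911 - 0.0130042 * T) * _DEG
    lam_r, beta_r = lam * _DEG, beta * _DEG
    ra = np.arctan2(
        np.sin(lam_r) * np.cos(eps) - np.tan(beta_r) * np.sin(eps),
        np.cos(lam_r),
    )
    dec = np.arcsin(
        np.sin(beta_r) * np.cos(eps)
        + np.cos(beta_r) * np.sin(eps) * np.sin(lam_r)
    )
    H = (_gmst(jd) + lon) * _DEG - ra
    phi = lat * _DEG
    alt = np.arcsin(
        np.sin(phi) * np.sin(dec) + np.cos(phi) * np.cos(dec) * np.cos(H)
    )
    # topocentric correction with the mean horizontal parallax
    alt_deg = alt / _DEG
    return float(alt_deg - 0.9508 * np.cos(alt))


def moon_rise_set_scan(date: dt.date, lon: float, lat: float,
                       standard_alt: float = 0.125):
    """(rise, set) times on `date` (UTC day) by 1-minute scanning of the
    oracle altitude; either may be None."""
    t0 = dt.datetime(date.year, date.month, date.day)
    alts = np.array(
        [
            moon_altitude(t0 + dt.timedelta(minutes=m), lon, lat)
            for m in range(0, 24 * 60 + 1, 1)
        ]
    ) - standard_alt
    rise = set_ = None
    for i in range(len(alts) - 1):
        if alts[i] <= 0 < alts[i + 1] and rise is None:
            f = alts[i] / (alts[i] - alts[i + 1])
            rise = t0 + dt.timedelta(minutes=i + f)
        if alts[i] > 0 >= alts[i + 1] and set_ is None:
            f = alts[i] / (alts[i] - alts[i + 1])
            set_ = t0 + dt.timedelta(minutes=i + f)
    return rise, set_


def day_length_bisection(sun_altitude_fn, date: dt.date, lat: float,
                         sun_elev: float) -> float:
    """Day length by brute-force bisection on the given sun-altitude
    function around local noon (longitude 0)."""
    from scipy.optimize import brentq

    noon = dt.datetime(date.year, date.month, date.day, 12)

    def alt_at(hours_from_noon):
        return (
            sun_altitude_fn(noon + dt.timedelta(hours=hours_from_noon), 0.0, lat)
            - sun_elev
        )

    if alt_at(0) < 0:
        return 0.0
    lo = brentq(alt_at, -12.0, 0.0)
    hi = brentq(alt_at, 0.0, 12.0)
    return hi - lo


def mixture_grid_search(x, n_mu=50, n_sd=20, n_w=19):
    """Best two-normal-mixture log-likelihood over a dense parameter grid
    (means x means x sds x sds x weights)."""
    x = np.asarray(x, dtype=float)
    mus = np.linspace(x.min(), x.max(), n_mu)
    sds = np.linspace(np.std(x) / 10.0, np.std(x), n_sd)
    ws = np.linspace(0.05, 0.95, n_w)
    best = -np.inf
    # vectorise over observations; loop the small grid
    for m1 in mus:
        pdf1 = {s1: stats.norm.pdf(x, m1, s1) for s1 in sds}
        for m2 in mus:
            if m2 < m1:
                continue
            pdf2 = {s2: stats.norm.pdf(x, m2, s2) for s2 in sds}
            for s1 in sds:
                p1 = pdf1[s1]
                for s2 in sds:
                    p2 = pdf2[s2]
                    for w in ws:
                        ll = np.sum(np.log(w * p1 + (1 - w) * p2 + 1e-300))
                        if ll > best:
                            best = ll
    return float(best)
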