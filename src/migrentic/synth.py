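"""Synthetic populations of migrating shearwaters with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: lay dates drive migratory departure, later departures shorten both
the stopover budget and the total migration, nightly flight is boosted by
moon illumination, and the raw sensor streams (light, wet/dry immersion)
are rendered from the true positions and behaviours so the whole pipeline
can be validated round-trip.

Generating equations (covariates on the scales the models use: departure as
days since Aug 1, lay as days since Apr 1, moon as illuminated fraction):

* ``departure = mean_departure + slope_departure_on_lay * (lay - mean_lay)
  + bird_effect + noise``
* ``total_stopover_days = stopover_days_base
  + slope_stopover_days_on_departure * (departure - mean_departure) + noise``
* ``duration = duration_base
  + slope_duration_on_departure * (departure - mean_departure)
  + duration_moon_effect * (mean_night_illumination - 0.5) + noise``
* on migrating (non-stopover) nights::

      night_flight = night_flight_base
                     + night_flight_moon_effect * illumination
                     + night_flight_departure_effect * departure
                     + night_flight_moon_departure_interaction
                       * illumination * departure
                     + bird_re + year_re + eps,   truncated to [0, night]

* on migrating days (daylight)::

      day_flight = (night_flight_base + 0.5 * night_flight_moon_effect
                    - day_night_flight_offset)
                   + day_flight_departure_effect * departure
                   + bird_re + year_re + eps,     truncated to [0, day]

  so that at the long-run mean illumination of 0.5 the day-night contrast
  equals ``day_night_flight_offset``.

Stopover days draw low daily flight totals from
``N(stopover_flighthours_mean, stopover_flighthours_sd)``; breeding and
wintering days behave like stopover days.  The trajectory is a great
circle from the colony to the centre of the wintering box, traversed at
constant daily displacement on travel days and frozen on stopover days.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import astro

__all__ = [
    "Colony",
    "PopulationParams",
    "TrueItinerary",
    "LightSeries",
    "ImmersionSeries",
    "LightNoise",
    "simulate_population",
    "simulate_flight_hours",
    "render_light",
    "render_immersion",
    "render_chl_grid",
    "DEFAULT_COLONIES",
]

BIN_MINUTES = 10
BINS_PER_HOUR = 60 // BIN_MINUTES

# behaviour codes for the 10-min bins
FLIGHT, FORAGE, REST = 0, 1, 2
BEHAVIOUR_NAMES = {FLIGHT: "flight", FORAGE: "forage", REST: "rest"}


class ParameterisationError(ValueError):
    """Raised when population parameters imply impossible itineraries."""


@dataclass(frozen=True)
class Colony:
    name: str
    lon: float
    lat: float


# coordinates as reported for the five UK study colonies
DEFAULT_COLONIES = (
    Colony("Copeland", -5.53, 54.68),
    Colony("Lundy", -4.67, 51.18),
    Colony("Ramsey", -5.29, 51.74),
    Colony("Rum", -6.33, 57.01),
    Colony("Skomer", -5.29, 51.74),
)
SKOMER = DEFAULT_COLONIES[4]


@dataclass(frozen=True)
class PopulationParams:
    """Generating parameters for one synthetic population.

    Defaults encode the study conditions: lay dates uniform on
    26 April - 6 June, mean departure 14 September, slopes equal to the
    field-estimated effect sizes, and a wintering box on the Patagonian shelf
    (46-36 deg S, 66-54 deg W).
    """

    n_birds: int = 89
    seed: int = 0
    years: tuple[int, ...] = (2014, 2015, 2016)
    colonies: tuple[Colony, ...] = (SKOMER,)
    lay_colony: str = "Skomer"  # only this colony's birds carry lay dates
    # phenology (dates for a nominal year; applied per bird-year)
    lay_date_range: tuple[tuple[int, int], tuple[int, int]] = ((4, 26), (6, 6))
    mean_departure: tuple[int, int] = (9, 14)
    slope_departure_on_lay: float = 0.566
    departure_bird_sd: float = 2.0
    departure_noise_sd: float = 1.5
    # stopover budget
    stopover_days_base: float = 10.07
    slope_stopover_days_on_departure: float = -0.156
    stopover_days_noise_sd: float = 0.5
    stopover_block_mean_days: float = 2.69
    # migration duration
    duration_base: float = 31.72
    slope_duration_on_departure: float = -0.323
    duration_moon_effect: float = -15.633
    duration_noise_sd: float = 0.8
    # nightly/daily flight behaviour (hours)
    night_flight_base: float = 2.106
    night_flight_moon_effect: float = 3.245
    night_flight_departure_effect: float = 0.015
    night_flight_moon_departure_interaction: float = 0.018
    day_night_flight_offset: float = -3.827
    day_flight_departure_effect: float = 0.001
    bird_random_sd: float = 0.5
    year_random_sd: float = 0.2
    residual_sd: float = 1.5
    # night foraging on migrating nights (hours)
    night_forage_base: float = 6.134
    night_forage_moon_effect: float = -2.846
    # stopover / resident behaviour (daily totals, hours)
    stopover_flighthours_mean: float = 3.0
    stopover_flighthours_sd: float = 1.0
    migration_flighthours_mean: float = 12.0
    migration_flighthours_sd: float = 1.5
    stopover_forage_base: float = 12.556
    stopover_forage_departure_effect: float = 0.010
    stopover_forage_noise_sd: float = 1.0
    # geography
    wintering_box: tuple[float, float, float, float] = (-66.0, -54.0, -46.0, -36.0)
    # rendered series extent (month, day)
    series_start: tuple[int, int] = (7, 15)
    series_end: tuple[int, int] = (12, 15)
    min_travel_days: int = 10
    lead_travel_days: int = 5  # travel before the first stopover
    tail_travel_days: int = 3  # travel after the last stopover

    def __post_init__(self):
        if self.n_birds < 1:
            raise ParameterisationError("n_birds must be >= 1")
        for name in (
            "departure_bird_sd", "departure_noise_sd", "stopover_days_noise_sd",
            "duration_noise_sd", "bird_random_sd", "year_random_sd",
            "residual_sd", "stopover_flighthours_sd", "migration_flighthours_sd",
        ):
            if getattr(self, name) < 0:
                raise ParameterisationError(f"{name} must be >= 0")
        if self.lay_date_range[0] > self.lay_date_range[1]:
            raise ParameterisationError("lay_date_range must be ordered")
        w = self.wintering_box
        if not (w[0] < w[1] and w[2] < w[3]):
            raise ParameterisationError("wintering_box must be ordered")
        if not self.colonies:
            raise ParameterisationError("at least one colony required")

    @property
    def wintering_centroid(self) -> tuple[float, float]:
        w = self.wintering_box
        return ((w[0] + w[1]) / 2.0, (w[2] + w[3]) / 2.0)


@dataclass
class LightSeries:
    """Raw light stream for one bird-year (regular sampling)."""

    bird_id: str
    times: np.ndarray  # datetime64[s]
    light: np.ndarray  # logger units, clipped at `max_light`
    max_light: float = 64.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.times, "light": self.light})


@dataclass
class ImmersionSeries:
    """Raw wet/dry stream for one bird-year at a fixed sub-minute interval."""

    bird_id: str
    times: np.ndarray  # datetime64[s]
    wet: np.ndarray  # bool
    sample_seconds: int = 3
    usable: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"timestamp": self.times, "wet": self.wet.astype(int)}
        )


@dataclass
class TrueItinerary:
    """Ground truth for one simulated bird-year."""

    bird_id: str
    year: int
    colony: Colony
    lay_date: dt.date | None
    departure_date: dt.date
    arrival_date: dt.date
    total_stopover_days: int
    days: pd.DataFrame  # per calendar day: state, lon, lat, hours, moon
    bin_times: np.ndarray  # datetime64[s], 10-min grid
    bin_behaviour: np.ndarray  # int8 codes FLIGHT/FORAGE/REST
    bin_date: np.ndarray  # index into `days`
    bin_is_night: np.ndarray  # bool
    bird_flight_re: float = 0.0
    year_flight_re: float = 0.0

    @property
    def duration_days(self) -> int:
        return (self.arrival_date - self.departure_date).days

    def day_table(self) -> pd.DataFrame:
        out = self.days.copy()
        out.insert(0, "bird_id", self.bird_id)
        out.insert(1, "year", self.year)
        out.insert(2, "colony", self.colony.name)
        return out


# ---------------------------------------------------------------------------
# geometry helpers


def _slerp(p0, p1, frac):
    """Great-circle interpolation between (lon, lat) points, degrees."""
    to_xyz = lambda lon, lat: np.array(
        [
            np.cos(np.radians(lat)) * np.cos(np.radians(lon)),
            np.cos(np.radians(lat)) * np.sin(np.radians(lon)),
            np.sin(np.radians(lat)),
        ]
    )
    a, b = to_xyz(*p0), to_xyz(*p1)
    omega = np.arccos(np.clip(a @ b, -1.0, 1.0))
    frac = np.atleast_1d(np.asarray(frac, dtype=float))
    if omega < 1e-12:
        xyz = np.tile(a, (len(frac), 1)).T
    else:
        xyz = (
            np.outer(a, np.sin((1 - frac) * omega))
            + np.outer(b, np.sin(frac * omega))
        ) / np.sin(omega)
    lon = np.degrees(np.arctan2(xyz[1], xyz[0]))
    lat = np.degrees(np.arcsin(np.clip(xyz[2] / np.linalg.norm(xyz, axis=0), -1, 1)))
    return lon, lat


def _date_in_year(year, month_day):
    return dt.date(year, *month_day)


# ---------------------------------------------------------------------------
# population simulation


def _stopover_blocks(total, travel, params, rng):
    """Return (block lengths, travel-day gaps) placing `total` stopover days
    among `travel` travel days; gaps has len(blocks)+1 entries."""
    lengths = []
    remaining = total
    p = 1.0 / params.stopover_block_mean_days
    while remaining > 0:
        L = min(int(rng.geometric(p)), remaining)
        lengths.append(L)
        remaining -= L
    n = len(lengths)
    lead, tail = params.lead_travel_days, params.tail_travel_days
    # shrink the block count if travel days cannot host the required gaps
    while n > 1 and travel < lead + tail + (n - 1):
        lengths[-2] += lengths[-1]
        lengths.pop()
        n -= 1
    spare = travel - lead - tail - max(n - 1, 0)
    if spare < 0:
        raise ParameterisationError(
            "not enough travel days to honour lead/tail gaps; "
            "duration/stopover parameterisation infeasible"
        )
    weights = rng.dirichlet(np.ones(n + 1)) if n else np.array([1.0])
    extra = np.floor(weights * spare).astype(int)
    extra[0] += spare - extra.sum()
    gaps = np.ones(n + 1, dtype=int)
    gaps[0] = lead
    gaps[-1] = tail
    if n >= 1:
        gaps[1:-1] = 1
    gaps = gaps + extra if n else np.array([travel])
    return lengths, list(gaps)


def _feasibility_check(params: PopulationParams):
    """Fail fast if the slopes make itineraries impossible anywhere in the
    lay-date range (zero-noise envelope, 3-sd noise margin)."""
    lay_lo = 0.0
    lay_hi = (
        _date_in_year(2000, params.lay_date_range[1])
        - _date_in_year(2000, params.lay_date_range[0])
    ).days
    mean_lay = (lay_lo + lay_hi) / 2.0
    for lay in (lay_lo, lay_hi):
        dev = params.slope_departure_on_lay * (lay - mean_lay)
        stop = params.stopover_days_base + params.slope_stopover_days_on_departure * dev
        dur = params.duration_base + params.slope_duration_on_departure * dev
        if dur - stop < params.min_travel_days:
            raise ParameterisationError(
                "duration/stopover slopes leave fewer than min_travel_days "
                f"travel days for in-range lay dates (lay offset {lay})"
            )


def simulate_population(params: PopulationParams) -> list[TrueItinerary]:
    """Simulate a population of bird-years with full ground truth."""
    _feasibility_check(params)
    root = np.random.SeedSequence(params.seed)
    pop_rng = np.random.default_rng(root.spawn(1)[0])
    bird_seeds = root.spawn(params.n_birds + 1)[1:]

    year_re = {
        y: pop_rng.normal(0.0, params.year_random_sd) for y in params.years
    }
    lay_lo = _date_in_year(2000, params.lay_date_range[0]).toordinal()
    lay_hi = _date_in_year(2000, params.lay_date_range[1]).toordinal()
    mean_lay_off = (lay_hi - lay_lo) / 2.0

    birds = []
    for i in range(params.n_birds):
        rng = np.random.default_rng(bird_seeds[i])
        year = params.years[i % len(params.years)]
        colony = params.colonies[i % len(params.colonies)]
        lay_offset = rng.uniform(0.0, lay_hi - lay_lo)
        lay_date = _date_in_year(year, params.lay_date_range[0]) + dt.timedelta(
            days=round(lay_offset)
        )
        bird_dep_eff = rng.normal(0.0, params.departure_bird_sd)
        dep_dev = (
            params.slope_departure_on_lay * (round(lay_offset) - mean_lay_off)
            + bird_dep_eff
            + rng.normal(0.0, params.departure_noise_sd)
        )
        departure = _date_in_year(year, params.mean_departure) + dt.timedelta(
            days=round(dep_dev)
        )
        if departure <= lay_date:
            raise ParameterisationError("departure before lay date")

        stop_total = params.stopover_days_base + (
            params.slope_stopover_days_on_departure * round(dep_dev)
        ) + rng.normal(0.0, params.stopover_days_noise_sd)
        stop_total = max(1, round(stop_total))

        dur0 = (
            params.duration_base
            + params.slope_duration_on_departure * round(dep_dev)
            + rng.normal(0.0, params.duration_noise_sd)
        )
        # moon exposure over the expected window given departure: nightly
        # illuminated fraction at local solar midnight along an approximate
        # route (illumination is global; position only shifts the midnight
        # instant by a few hours)
        L = max(round(dur0), 1)
        lons = colony.lon + (
            params.wintering_centroid[0] - colony.lon
        ) * np.arange(L) / max(L - 1, 1)
        mean_illum = float(
            np.mean(
                [
                    astro.night_illumination(
                        departure + dt.timedelta(days=int(k)), lons[k]
                    )
                    for k in range(L)
                ]
            )
        )
        duration = round(dur0 + params.duration_moon_effect * (mean_illum - 0.5))
        duration = max(duration, stop_total + params.min_travel_days)

        itin = _build_itinerary(
            params,
            rng,
            bird_id=f"{colony.name[:3].upper()}_{i:03d}_{year}",
            year=year,
            colony=colony,
            lay_date=lay_date if colony.name == params.lay_colony else None,
            departure=departure,
            duration=duration,
            stop_total=stop_total,
            bird_flight_re=rng.normal(0.0, params.bird_random_sd),
            year_flight_re=year_re[year],
        )
        birds.append(itin)
    return birds


def _phase_hours(params, rng, state, dep_days, illum, day_len, night_len,
                 bird_re, year_re):
    """Draw (day flight, night flight, day forage, night forage) hours."""
    if state == "migrating":
        day_base = (
            params.night_flight_base
            + 0.5 * params.night_flight_moon_effect
            - params.day_night_flight_offset
        )
        df = (
            day_base
            + params.day_flight_departure_effect * dep_days
            + bird_re + year_re
            + rng.normal(0.0, params.residual_sd)
        )
        nf = (
            params.night_flight_base
            + params.night_flight_moon_effect * illum
            + params.night_flight_departure_effect * dep_days
            + params.night_flight_moon_departure_interaction * illum * dep_days
            + bird_re + year_re
            + rng.normal(0.0, params.residual_sd)
        )
        nfor = (
            params.night_forage_base
            + params.night_forage_moon_effect * illum
            + rng.normal(0.0, params.residual_sd)
        )
        dfor = rng.normal(6.0, 1.5)
    else:  # stopover / breeding / wintering: low-flight, forage-heavy
        total = rng.normal(
            params.stopover_flighthours_mean, params.stopover_flighthours_sd
        )
        total = float(np.clip(total, 0.2, None))
        night_share = rng.uniform(0.3, 0.5)
        df, nf = total * (1 - night_share), total * night_share
        ftot = (
            params.stopover_forage_base
            + params.stopover_forage_departure_effect * dep_days
            + rng.normal(0.0, params.stopover_forage_noise_sd)
        )
        frac_day = day_len / (day_len + night_len)
        dfor, nfor = ftot * frac_day, ftot * (1 - frac_day)
    df = float(np.clip(df, 0.0, day_len))
    nf = float(np.clip(nf, 0.0, night_len))
    dfor = float(np.clip(dfor, 0.0, day_len - df))
    nfor = float(np.clip(nfor, 0.0, night_len - nf))
    return df, nf, dfor, nfor


def _build_itinerary(params, rng, *, bird_id, year, colony, lay_date,
                     departure, duration, stop_total, bird_flight_re,
                     year_flight_re):
    start = _date_in_year(year, params.series_start)
    end = _date_in_year(year, params.series_end)
    arrival = departure + dt.timedelta(days=duration)
    if arrival >= end:
        arrival = end - dt.timedelta(days=1)
        duration = (arrival - departure).days
    travel = duration - stop_total

    dates = pd.date_range(start, end, freq="D").date
    n_days = len(dates)
    state = np.array(["breeding"] * n_days, dtype=object)
    mig0 = (departure - start).days
    mig1 = (arrival - start).days
    state[mig1:] = "wintering"

    blocks, gaps = _stopover_blocks(stop_total, travel, params, rng)
    labels = []
    for g, b in zip(gaps, blocks + [0]):
        labels.extend(["migrating"] * g)
        labels.extend(["stopover"] * b)
    labels = labels[:duration] + ["migrating"] * max(0, duration - len(labels))
    state[mig0:mig1] = labels[: mig1 - mig0]

    # positions: great circle, advanced only on migrating days
    frac = np.zeros(n_days)
    trav_count = np.cumsum(
        [1 if s == "migrating" else 0 for s in state[mig0:mig1]]
    )
    n_trav = max(trav_count[-1], 1) if len(trav_count) else 1
    frac[mig0:mig1] = np.minimum(trav_count / n_trav, 1.0)
    frac[mig1:] = 1.0
    lon, lat = _slerp(
        (colony.lon, colony.lat), params.wintering_centroid, frac
    )

    # per-day phases at the true position
    sunrise = np.empty(n_days, dtype="datetime64[s]")
    sunset = np.empty(n_days, dtype="datetime64[s]")
    next_sunrise = np.empty(n_days, dtype="datetime64[s]")
    for k, d in enumerate(dates):
        r, s = astro.sun_events(d, lon[k], lat[k], "horizon")
        sunrise[k] = np.datetime64(r.time.replace(tzinfo=None), "s")
        sunset[k] = np.datetime64(s.time.replace(tzinfo=None), "s")
        r2, _ = astro.sun_events(
            d + dt.timedelta(days=1), lon[k], lat[k], "horizon"
        )
        next_sunrise[k] = np.datetime64(r2.time.replace(tzinfo=None), "s")
    day_len = (sunset - sunrise).astype(float) / 3600.0
    night_len = (next_sunrise - sunset).astype(float) / 3600.0

    # per-night moon illumination at local solar midnight
    midnights = sunset + ((next_sunrise - sunset) / 2)
    illum = np.asarray(astro.moon_illumination(midnights))

    dep_days = (departure - dt.date(year, 8, 1)).days
    # behavioural covariate centred on the population mean departure, so
    # the moon main effect is the effect at an average departure date
    dep_c = dep_days - (
        _date_in_year(year, params.mean_departure) - dt.date(year, 8, 1)
    ).days

    cols = dict(
        date=dates, state=state, lon=lon, lat=lat,
        day_length_h=day_len, night_length_h=night_len,
        night_illumination=illum,
        sunrise=sunrise, sunset=sunset, next_sunrise=next_sunrise,
    )
    hours = np.zeros((n_days, 4))
    for k in range(n_days):
        hours[k] = _phase_hours(
            params, rng, state[k], dep_c, illum[k],
            day_len[k], night_len[k], bird_flight_re, year_flight_re,
        )
    cols.update(
        day_flight_h=hours[:, 0], night_flight_h=hours[:, 1],
        day_forage_h=hours[:, 2], night_forage_h=hours[:, 3],
    )
    days = pd.DataFrame(cols)
    days["departure_days_since_aug1"] = dep_days
    days["departure_centred"] = dep_c

    bin_times, beh, bin_date, bin_is_night = _assign_bins(days, rng)
    return TrueItinerary(
        bird_id=bird_id, year=year, colony=colony, lay_date=lay_date,
        departure_date=departure, arrival_date=arrival,
        total_stopover_days=int(np.sum(state == "stopover")),
        days=days, bin_times=bin_times, bin_behaviour=beh,
        bin_date=bin_date, bin_is_night=bin_is_night,
        bird_flight_re=bird_flight_re, year_flight_re=year_flight_re,
    )


def _assign_bins(days: pd.DataFrame, rng) -> tuple:
    """Lay out 10-min behaviour bins over the whole series.

    Flight is placed as one contiguous run per phase (so continuous-flight
    metrics are meaningful), forage bins are scattered over the remainder,
    everything else rests on the water.
    """
    t0 = np.datetime64(days["date"].iloc[0], "s")
    t1 = np.datetime64(days["date"].iloc[-1] + dt.timedelta(days=2), "s")
    step = np.timedelta64(BIN_MINUTES * 60, "s")
    bin_times = np.arange(t0, t1, step)
    mid = bin_times + step // 2
    beh = np.full(len(bin_times), REST, dtype=np.int8)
    bin_date = np.full(len(bin_times), -1, dtype=np.int64)
    bin_is_night = np.zeros(len(bin_times), dtype=bool)

    for k in range(len(days)):
        row = days.iloc[k]
        for is_night, (a, b), fh, gh in (
            (False, (row.sunrise, row.sunset), row.day_flight_h, row.day_forage_h),
            (True, (row.sunset, row.next_sunrise), row.night_flight_h, row.night_forage_h),
        ):
            idx = np.nonzero((mid >= a) & (mid < b))[0]
            if len(idx) == 0:
                continue
            bin_date[idx] = k
            bin_is_night[idx] = is_night
            nf = min(int(round(fh * BINS_PER_HOUR)), len(idx))
            ng = min(int(round(gh * BINS_PER_HOUR)), len(idx) - nf)
            start = rng.integers(0, len(idx) - nf + 1) if nf < len(idx) else 0
            flight_idx = idx[start : start + nf]
            beh[flight_idx] = FLIGHT
            rest_pool = np.setdiff1d(idx, flight_idx)
            if ng > 0:
                forage_idx = rng.choice(rest_pool, size=ng, replace=False)
                beh[forage_idx] = FORAGE
    return bin_times, beh, bin_date, bin_is_night


def simulate_flight_hours(n, params: PopulationParams | None = None, seed=0):
    """Simplified draw of pooled daily flight-hour totals from the
    two-component generating mixture (stopover vs migrating days); used to
    exercise the mixture fitter in isolation.  Returns (values, labels)
    with label 1 = stopover (low) component."""
    params = params or PopulationParams()
    rng = np.random.default_rng(seed)
    frac_stop = params.stopover_days_base / params.duration_base
    lab = rng.random(n) < frac_stop
    vals = np.where(
        lab,
        rng.normal(params.stopover_flighthours_mean,
                   params.stopover_flighthours_sd, n),
        rng.normal(params.migration_flighthours_mean,
                   params.migration_flighthours_sd, n),
    )
    return np.clip(vals, 0.0, 24.0), lab.astype(int)


# ---------------------------------------------------------------------------
# sensor rendering


@dataclass(frozen=True)
class LightNoise:
    """Noise model for rendered light: multiplicative log-normal noise and
    random shading events (dark intervals from e.g. feather coverage)."""

    sigma: float = 0.0  # log-scale multiplicative noise
    shade_prob: float = 0.0  # per-sample probability a shading event starts
    shade_mean_bins: float = 3.0  # mean shading duration in samples
    shade_factor: float = 0.02  # light multiplier while shaded
    seed: int = 0


def render_light(itinerary: TrueItinerary,
                 noise: LightNoise | None = None,
                 sample_minutes: int = BIN_MINUTES,
                 max_light: float = 64.0,
                 threshold_elev: float = -4.5,
                 logistic_width: float = 1.0) -> LightSeries:
    """Render a light series from the true positions.

    Light is a saturating logistic function of sun altitude, centred on
    ``threshold_elev`` so that light == max_light/2 exactly when the sun
    sits at the geolocation threshold elevation.
    """
    noise = noise or LightNoise()
    days = itinerary.days
    t0 = np.datetime64(days["date"].iloc[0], "s")
    t1 = np.datetime64(days["date"].iloc[-1] + dt.timedelta(days=2), "s")
    step = np.timedelta64(sample_minutes * 60, "s")
    times = np.arange(t0, t1, step)
    day_idx = np.clip(
        ((times - t0) / np.timedelta64(1, "D")).astype(int), 0, len(days) - 1
    )
    lon = days["lon"].to_numpy()[day_idx]
    lat = days["lat"].to_numpy()[day_idx]
    alt = np.asarray(astro.sun_altitude(times, lon, lat))
    light = max_light / (1.0 + np.exp(-(alt - threshold_elev) / logistic_width))

    rng = np.random.default_rng(noise.seed)
    if noise.sigma > 0:
        light = light * rng.lognormal(0.0, noise.sigma, len(light))
    if noise.shade_prob > 0:
        starts = rng.random(len(light)) < noise.shade_prob
        for s in np.nonzero(starts)[0]:
            dur = rng.geometric(1.0 / noise.shade_mean_bins)
            light[s : s + dur] *= noise.shade_factor
    return LightSeries(
        bird_id=itinerary.bird_id,
        times=times,
        light=np.clip(light, 0.0, max_light),
        max_light=max_light,
    )


def render_immersion(itinerary: TrueItinerary, sample_seconds: int = 3,
                     seed: int = 0) -> ImmersionSeries:
    """Render raw wet/dry samples from the per-bin true behaviour.

    Flight bins are fully dry, rest bins fully wet, forage bins carry a wet
    fraction strictly inside (0, 1) so the summed 10-min score is always
    intermediate.
    """
    if (BIN_MINUTES * 60) % sample_seconds != 0:
        raise ValueError("sample_seconds must divide the 10-min bin exactly")
    per_bin = BIN_MINUTES * 60 // sample_seconds
    rng = np.random.default_rng(seed)
    beh = itinerary.bin_behaviour
    n_bins = len(beh)

    wet = np.zeros((n_bins, per_bin), dtype=bool)
    wet[beh == REST] = True
    forage = np.nonzero(beh == FORAGE)[0]
    if len(forage):
        p = rng.uniform(0.15, 0.85, size=len(forage))
        w = rng.random((len(forage), per_bin)) < p[:, None]
        # force a strictly intermediate score
        w[:, 0] = True
        w[:, -1] = False
        wet[forage] = w

    step = np.timedelta64(sample_seconds, "s")
    times = (
        itinerary.bin_times[:, None]
        + np.arange(per_bin) * step
    ).ravel()
    return ImmersionSeries(
        bird_id=itinerary.bird_id,
        times=times,
        wet=wet.ravel(),
        sample_seconds=sample_seconds,
    )


# ---------------------------------------------------------------------------
# chlorophyll grid


def render_chl_grid(extent, dates, gradient_params=None, seed=0,
                    resolution=0.5, missing_fraction=0.0):
    """Daily gridded chlorophyll-a field (mg m^-3) as an xarray.DataArray.

    extent: (lon_min, lon_max, lat_min, lat_max) degrees.
    dates: iterable of datetime.date (daily).
    gradient_params: dict with keys
        base        value at lat 0 at the season start (default 0.5)
        lat_coef    exponential latitudinal gradient per degree (default -0.01,
                    i.e. richer toward the south)
        seasonal_decline  fractional decline per day after Aug 1 applied to
                    northern-hemisphere cells (default 0.004)
    Cells masked as missing (cloud) are NaN.
    """
    lon_min, lon_max, lat_min, lat_max = extent
    if not (lon_min < lon_max and lat_min < lat_max):
        raise ValueError("empty extent")
    import xarray as xr

    gp = {"base": 0.5, "lat_coef": -0.01, "seasonal_decline": 0.004}
    gp.update(gradient_params or {})
    lons = np.arange(lon_min, lon_max + resolution / 2, resolution)
    lats = np.arange(lat_min, lat_max + resolution / 2, resolution)
    dates = list(dates)
    if not dates:
        raise ValueError("empty date range")
    aug1 = dt.date(dates[0].year, 8, 1)
    tday = np.array([(d - aug1).days for d in dates], dtype=float)

    lat_field = gp["base"] * np.exp(gp["lat_coef"] * lats)[:, None]
    lat_field = np.broadcast_to(lat_field, (len(lats), len(lons)))
    north = (lats > 0)[:, None]
    data = np.empty((len(dates), len(lats), len(lons)))
    for i, td in enumerate(tday):
        seas = np.where(
            north, np.clip(1.0 - gp["seasonal_decline"] * max(td, 0.0), 0.05, None), 1.0
        )
        data[i] = lat_field * seas
    if missing_fraction > 0:
        rng = np.random.default_rng(seed)
        mask = rng.random(data.shape) < missing_fraction
        data = np.where(mask, np.nan, data)
    return xr.DataArray(
        data,
        dims=("date", "lat", "lon"),
        coords={
            "date": pd.to_datetime(dates),
            "lat": lats,
            "lon": lons,
        },
        name="chlor_a",
        attrs={"units": "mg m-3"},
    )


# ---------------------------------------------------------------------------
# writers


def write_series(series, path):
    """Write a Light/ImmersionSeries as headered delimited text."""
    df = series.to_frame()
    df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    df.to_csv(path, index=False)


def itineraries_to_frame(itins: list[TrueItinerary]) -> pd.DataFrame:
    """Tidy per-bird summary of ground truth (one row per bird-year)."""
    rows = []
    for it in itins:
        rows.append(
            {
                "bird_id": it.bird_id,
                "year": it.year,
                "colony": it.colony.name,
                "lay_date": it.lay_date,
                "departure_date": it.departure_date,
                "arrival_date": it.arrival_date,
                "duration_days": it.duration_days,
                "total_stopover_days": it.total_stopover_days,
            }
        )
    return pd.DataFrame(rows)
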