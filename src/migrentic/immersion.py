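"""Wet/dry immersion scores, behaviour classification and the bird-day table.

Raw immersion samples are summed into 10-min scores scaled to 0-200:
0 = dry for the whole bin (flight), 200 = wet throughout (resting on the
water), intermediate scores 1-199 = foraging.  Bins are aligned to the UTC
clock; bins straddling a twilight are split pro-rata between day and night.
The output is one row per (bird, date, phase) carrying flight and foraging
hours, phase length, and for night rows the moon covariates — the unit of
the mixed-effects models.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import astro
from .astro import SolarEvent
from .synth import ImmersionSeries, BIN_MINUTES, BINS_PER_HOUR

__all__ = [
    "ImmersionConfig",
    "bin_scores",
    "classify_bin",
    "split_day_night",
    "daily_metrics",
    "build_birdday_table",
]

FLIGHT, FORAGE, REST = "flight", "forage", "rest"


@dataclass(frozen=True)
class ImmersionConfig:
    bin_minutes: int = BIN_MINUTES
    max_score: int = 200
    forage_low: int = 1
    forage_high: int = 199

    def __post_init__(self):
        if not (0 < self.forage_low <= self.forage_high < self.max_score):
            raise ValueError("forage bounds must satisfy 0 < low <= high < max")


def bin_scores(raw: ImmersionSeries, cfg: ImmersionConfig | None = None) -> pd.DataFrame:
    """Sum wet samples into UTC-clock-aligned bins, scaled to [0, max_score].

    Returns columns bin_start, score, missing; bins with no samples are
    flagged missing (score NaN).
    """
    cfg = cfg or ImmersionConfig()
    bin_s = cfg.bin_minutes * 60
    if bin_s % raw.sample_seconds != 0:
        raise ValueError("sampling interval must divide the bin length")
    per_bin = bin_s // raw.sample_seconds
    t = raw.times.astype("datetime64[s]")
    secs = t.astype("int64")
    bin_ids = secs // bin_s
    first, last = bin_ids[0], bin_ids[-1]
    n_bins = int(last - first + 1)
    counts = np.bincount((bin_ids - first).astype(int), minlength=n_bins)
    wet_counts = np.bincount(
        (bin_ids - first).astype(int), weights=raw.wet.astype(float),
        minlength=n_bins,
    )
    missing = counts < per_bin
    with np.errstate(invalid="ignore", divide="ignore"):
        score = wet_counts * (cfg.max_score / per_bin)
    score = np.where(missing, np.nan, score)
    starts = (np.arange(first, last + 1) * bin_s).astype("datetime64[s]")
    return pd.DataFrame(
        {"bin_start": starts, "score": score, "missing": missing}
    )


def classify_bin(score, cfg: ImmersionConfig | None = None) -> str:
    """0 -> flight, [forage_low, forage_high] -> forage, max_score -> rest."""
    cfg = cfg or ImmersionConfig()
    if score < 0 or score > cfg.max_score:
        raise ValueError(f"score {score} outside [0, {cfg.max_score}]")
    if score < cfg.forage_low:
        return FLIGHT
    if score <= cfg.forage_high:
        return FORAGE
    return REST


def _classify_scores(scores: np.ndarray, cfg: ImmersionConfig) -> np.ndarray:
    out = np.full(len(scores), REST, dtype=object)
    out[scores < cfg.forage_low] = FLIGHT
    out[(scores >= cfg.forage_low) & (scores <= cfg.forage_high)] = FORAGE
    out[~np.isfinite(scores)] = "missing"
    return out


def split_day_night(bins: pd.DataFrame, twilights: list[SolarEvent],
                    fallback_position=None) -> pd.DataFrame:
    """Assign each bin a bird-date and pro-rata day/night fractions.

    The bird-day for calendar date d spans sunrise(d) .. sunrise(d+1):
    the daylight phase sunrise(d)->sunset(d) and the following night
    sunset(d)->sunrise(d+1).  A bin straddling a twilight contributes
    fractionally to both phases.  Dates with no detected twilights fall
    back to astronomical prediction at ``fallback_position`` (lon, lat)
    when given, else the bins are left unassigned.
    """
    bins = bins.copy()
    ev = sorted(twilights, key=lambda e: e.time)
    rises = [e for e in ev if e.event == "sunrise"]
    sets_ = [e for e in ev if e.event == "sunset"]
    rise_by_date = {e.time.date(): e.time for e in rises}
    set_by_date = {e.time.date(): e.time for e in sets_}

    s_arr = bins["bin_start"].to_numpy().astype("datetime64[s]")
    e_arr = s_arr + np.timedelta64(BIN_MINUTES * 60, "s")
    dates = sorted({d for d in s_arr.astype("datetime64[D]").tolist()})
    if dates:
        # the night preceding the first bins belongs to the previous
        # calendar day's bird-day
        dates = [dates[0] - dt.timedelta(days=1)] + dates
    day_frac = np.zeros(len(bins))
    night_frac = np.zeros(len(bins))
    bird_date = np.full(len(bins), None, dtype=object)

    def _naive64(t):
        if t.tzinfo is not None:
            t = t.astimezone(dt.timezone.utc).replace(tzinfo=None)
        return np.datetime64(t, "s")

    def interval_overlap(a0, a1):
        lo = np.maximum(s_arr, _naive64(a0))
        hi = np.minimum(e_arr, _naive64(a1))
        return np.clip(
            (hi - lo) / np.timedelta64(1, "s"), 0.0, None
        ) / (BIN_MINUTES * 60.0)

    for d in dates:
        sr = rise_by_date.get(d)
        ss = set_by_date.get(d)
        sr_next = rise_by_date.get(d + dt.timedelta(days=1))
        if sr is None or ss is None:
            if fallback_position is None:
                continue
            lon, lat = fallback_position
            r, s = astro.sun_events(d, lon, lat, "horizon")
            if r is None:
                continue
            sr = sr or r.time
            ss = ss or s.time
        if sr_next is None:
            if fallback_position is not None:
                r2, _ = astro.sun_events(
                    d + dt.timedelta(days=1), *fallback_position, "horizon"
                )
                sr_next = r2.time if r2 else ss + dt.timedelta(hours=12)
            else:
                sr_next = ss + dt.timedelta(hours=12)
        df = interval_overlap(sr, ss)
        nf = interval_overlap(ss, sr_next)
        sel = (df > 0) | (nf > 0)
        day_frac[sel] += df[sel]
        night_frac[sel] += nf[sel]
        bird_date[sel] = np.where(
            pd.isna(bird_date[sel]), d, bird_date[sel]
        )
        # bins fully within this bird-day belong to date d even if they
        # already brushed the previous day's night
        core = (df + nf) >= 0.999
        bird_date[core] = d
    bins["bird_date"] = bird_date
    bins["day_frac"] = day_frac
    bins["night_frac"] = night_frac
    return bins


def daily_metrics(bins: pd.DataFrame, bird_id: str,
                  cfg: ImmersionConfig | None = None,
                  moon: pd.DataFrame | None = None) -> tuple[pd.DataFrame, float]:
    """Collapse phase-labelled bins into per (date, phase) rows.

    Returns (table, max_continuous_flight_hours).  ``moon`` may carry
    per-date columns moon_illumination / moon_up_fraction merged onto
    night rows.  flight/forage hours use the pro-rata phase fractions;
    missing bins are excluded from the sums and from phase length.
    """
    cfg = cfg or ImmersionConfig()
    bins = bins[~pd.isna(bins["bird_date"])].copy()
    beh = _classify_scores(bins["score"].to_numpy(dtype=float), cfg)
    bins["behaviour"] = beh

    # longest run of consecutive flight bins, midnight crossings allowed
    is_flight = (beh == FLIGHT).astype(int)
    max_run = run = 0
    for v, m in zip(is_flight, bins["missing"].to_numpy()):
        run = run + 1 if (v and not m) else 0
        max_run = max(max_run, run)
    max_continuous_h = max_run / BINS_PER_HOUR

    rows = []
    for date, grp in bins.groupby("bird_date"):
        for phase, frac_col in (("day", "day_frac"), ("night", "night_frac")):
            ok = grp[~grp["missing"]]
            frac = ok[frac_col].to_numpy()
            b = ok["behaviour"].to_numpy()
            phase_len = frac.sum() / BINS_PER_HOUR
            if phase_len <= 0:
                continue
            fh = frac[b == FLIGHT].sum() / BINS_PER_HOUR
            gh = frac[b == FORAGE].sum() / BINS_PER_HOUR
            rows.append(
                {
                    "bird_id": bird_id,
                    "date": date,
                    "phase": phase,
                    "phase_length_h": phase_len,
                    "flight_hours": fh,
                    "forage_hours": gh,
                    "flight_proportion": fh / phase_len,
                }
            )
    table = pd.DataFrame(rows)
    if moon is not None and not table.empty:
        table = table.merge(moon, on="date", how="left")
        is_day = table["phase"] == "day"
        for c in ("moon_illumination", "moon_up_fraction"):
            if c in table:
                table.loc[is_day, c] = np.nan
    return table, max_continuous_h


def build_birdday_table(raw: ImmersionSeries, twilights: list[SolarEvent],
                        cfg: ImmersionConfig | None = None,
                        moon: pd.DataFrame | None = None,
                        fallback_position=None) -> tuple[pd.DataFrame, float]:
    """Full conversion raw immersion -> per bird-day/night metrics table."""
    cfg = cfg or ImmersionConfig()
    scored = bin_scores(raw, cfg)
    labelled = split_day_night(scored, twilights, fallback_position)
    return daily_metrics(labelled, raw.bird_id, cfg, moon)
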