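"""End-to-end orchestration: synth -> geolocate -> immersion -> stopover ->
enviro -> models, with QC filtering, per-stage logging and a reproducibility
manifest.

The analysis unit produced along the way:

* ``tracks``: PositionTrack per bird with detected migration window;
* ``birdday``: one row per (bird, date, day|night) inside the migration
  window with flight/forage hours, moon covariates and the stopover flag;
* ``birds``: one row per bird-year with phenology, stopover budget,
  mean moon, chlorophyll ratio and (where known) lay date;
* ``model_report``: the ten-model coefficient table.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import astro, enviro, geolocate, immersion, models, stopover, synth

__all__ = ["RunConfig", "qc_filter", "run_all", "process_bird", "summarise"]

log = logging.getLogger("migrentic")


@dataclass
class RunConfig:
    params: synth.PopulationParams = field(default_factory=synth.PopulationParams)
    geo: geolocate.GeolocationConfig = field(
        default_factory=geolocate.GeolocationConfig
    )
    imm: immersion.ImmersionConfig = field(default_factory=immersion.ImmersionConfig)
    stop: stopover.StopoverConfig = field(default_factory=stopover.StopoverConfig)
    chl: enviro.ChlConfig = field(default_factory=enviro.ChlConfig)
    light_noise: synth.LightNoise = field(default_factory=synth.LightNoise)
    seed: int = 1
    n_boot: int = 1000
    do_lrt: bool = True
    with_chlorophyll: bool = True
    immersion_sample_seconds: int = 3
    out_dir: str | None = None

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, (dt.date, dt.datetime)):
                return o.isoformat()
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def process_bird(itin: synth.TrueItinerary, cfg: RunConfig,
                 rng: np.random.Generator):
    """Render sensors for one bird and run geolocation + activity.

    Returns (track, birdday table, max_continuous_flight) — the bird-day
    table covers all days; migration-window restriction happens later.
    """
    noise = dataclasses.replace(
        cfg.light_noise, seed=int(rng.integers(0, 2**31 - 1))
    )
    light = synth.render_light(
        itin, noise, threshold_elev=cfg.geo.sun_elev,
        max_light=2 * cfg.geo.light_threshold,
    )
    imm_series = synth.render_immersion(
        itin, cfg.immersion_sample_seconds,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    twilights = geolocate.detect_twilights(light, cfg.geo)
    track = geolocate.build_track(itin.bird_id, twilights, cfg.geo)

    moon = None
    if not track.incomplete:
        moon = _moon_covariates(track, cfg)
    fallback = _fallback_position(track)
    birdday, max_cont = immersion.build_birdday_table(
        imm_series, twilights, cfg.imm, moon, fallback
    )
    return track, birdday, max_cont


def _fallback_position(track: geolocate.PositionTrack):
    if track.positions.empty:
        return None
    lon = float(track.daily_lon.iloc[0])
    lat_series = track.positions["lat"].dropna()
    lat = float(lat_series.iloc[0]) if not lat_series.empty else 45.0
    return lon, lat


def _estimated_daily_position(track: geolocate.PositionTrack) -> pd.DataFrame:
    pos = track.positions
    lat = (
        pos[~pos["equinox_flag"]].groupby("date")["lat"].mean()
    )
    daily = pd.DataFrame({"lon": track.smoothed_lon})
    daily["lat"] = lat
    daily["lat"] = daily["lat"].interpolate(limit_direction="both")
    return daily


def _moon_covariates(track: geolocate.PositionTrack, cfg: RunConfig) -> pd.DataFrame:
    """Per-night moon illumination and moon-up fraction at the estimated
    position, for the migration window (plus margin)."""
    daily = _estimated_daily_position(track)
    start = track.migration_start - dt.timedelta(days=2)
    end = track.migration_end + dt.timedelta(days=2)
    rows = []
    for d, row in daily.iterrows():
        if d < start or d > end or not np.isfinite(row["lat"]):
            continue
        states = astro.moon_windows(d, row["lon"], row["lat"])
        up = float(np.mean([s.risen for s in states])) if states else np.nan
        rows.append(
            {
                "date": d,
                "moon_illumination": astro.night_illumination(d, row["lon"]),
                "moon_up_fraction": up,
            }
        )
    return pd.DataFrame(rows)


def qc_filter(tracks: dict, birdday: dict) -> tuple[dict, dict, pd.DataFrame]:
    """Drop birds whose migration window could not be detected.

    Returns (kept tracks, kept birdday tables, exclusion log).
    """
    kept_t, kept_b, rows = {}, {}, []
    for bid, tr in tracks.items():
        if tr.incomplete:
            reason = (
                "no migration start detected"
                if tr.migration_start is None
                else "no migration end detected"
            )
            rows.append({"bird_id": bid, "reason": reason})
            log.warning("excluded %s: %s", bid, reason)
            continue
        kept_t[bid] = tr
        kept_b[bid] = birdday[bid]
    return kept_t, kept_b, pd.DataFrame(rows, columns=["bird_id", "reason"])


def _window_birdday(birdday: pd.DataFrame, track) -> pd.DataFrame:
    sel = (birdday["date"] >= track.migration_start) & (
        birdday["date"] < track.migration_end
    )
    return birdday[sel].copy()


def run_all(cfg: RunConfig) -> dict:
    """Run the full pipeline on a synthetic population.

    Returns a results bundle: tracks, birdday, birds, mixture fit,
    stopover sets, model report, Table-1-style summary, exclusion log and
    manifest.  Deterministic given the config (including seeds).
    """
    rng = np.random.default_rng(cfg.seed)
    population = synth.simulate_population(cfg.params)
    truth = synth.itineraries_to_frame(population)

    tracks, birdday_all, maxcont = {}, {}, {}
    for itin in population:
        track, bd, mc = process_bird(itin, cfg, rng)
        tracks[itin.bird_id] = track
        birdday_all[itin.bird_id] = bd
        maxcont[itin.bird_id] = mc
    tracks, birdday_all, exclusions = qc_filter(tracks, birdday_all)

    # --- stopover detection on pooled migration-window bird-days
    window_tables = {
        bid: _window_birdday(bd, tracks[bid]) for bid, bd in birdday_all.items()
    }
    totals = pd.concat(
        [stopover.daily_flight_totals(bd) for bd in window_tables.values()
         if not bd.empty],
        ignore_index=True,
    )
    mixture = stopover.fit_mixture_em(
        totals["flight_hours_total"].to_numpy(), cfg.stop
    )
    totals["is_stopover_day"] = stopover.assign_stopover_days(
        mixture, totals["flight_hours_total"].to_numpy(), cfg.stop
    )
    stop_sets = {}
    for bid, grp in totals.groupby("bird_id"):
        grp = grp.sort_values("date")
        stop_sets[bid] = stopover.segment_stopovers(
            list(grp["date"]), grp["is_stopover_day"].to_numpy(),
            tracks[bid], bid,
        )

    # --- chlorophyll
    chl_birds = None
    if cfg.with_chlorophyll and stop_sets:
        all_dates = sorted(
            {d for bd in window_tables.values() for d in bd["date"]}
        )
        grid = synth.render_chl_grid(
            extent=(-75.0, 5.0, -50.0, 60.0),
            dates=all_dates,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        chl_birds = enviro.bird_mean_ratios(
            list(stop_sets.values()), grid, cfg.chl
        )

    # --- assemble modelling tables
    birdday = _assemble_birdday(window_tables, totals, tracks, population)
    birds = _assemble_birds(
        tracks, stop_sets, birdday, population, chl_birds
    )

    report = models.run_model_suite(
        {"birdday": birdday, "birds": birds},
        n_boot=cfg.n_boot, seed=cfg.seed, do_lrt=cfg.do_lrt,
    )
    summary = summarise(birds, stop_sets, maxcont)

    manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_birds_simulated": len(population),
        "n_birds_kept": len(tracks),
        "tables_hash": _tables_hash(
            {"birdday": birdday, "birds": birds, "summary": summary}
        ),
    }
    bundle = {
        "population": population,
        "truth": truth,
        "tracks": tracks,
        "birdday": birdday,
        "birds": birds,
        "mixture": mixture,
        "stopover_sets": stop_sets,
        "model_report": report,
        "summary": summary,
        "exclusions": exclusions,
        "manifest": manifest,
    }
    if cfg.out_dir:
        _write_bundle(bundle, Path(cfg.out_dir))
    return bundle


def _assemble_birdday(window_tables, totals, tracks, population) -> pd.DataFrame:
    meta = {
        it.bird_id: (it.colony.name, it.year) for it in population
    }
    flags = totals.set_index(["bird_id", "date"])["is_stopover_day"]
    frames = []
    for bid, bd in window_tables.items():
        if bd.empty:
            continue
        bd = bd.copy()
        colony, year = meta[bid]
        bd["colony"] = colony
        bd["year"] = year
        bd["bird"] = bid.rsplit("_", 1)[0]
        start = tracks[bid].migration_start
        dep_abs = (start - dt.date(start.year, 8, 1)).days
        bd["departure_abs"] = dep_abs
        key = pd.MultiIndex.from_arrays([bd["bird_id"], bd["date"]])
        bd["is_stopover_day"] = flags.reindex(key).to_numpy()
        bd = bd.dropna(subset=["is_stopover_day"])
        bd["is_stopover_day"] = bd["is_stopover_day"].astype(bool)
        frames.append(bd)
    out = pd.concat(frames, ignore_index=True)
    out["dep_c"] = out["departure_abs"] - out["departure_abs"].mean()
    out["days_since_aug1"] = [
        (d - dt.date(d.year, 8, 1)).days for d in out["date"]
    ]
    return out


def _assemble_birds(tracks, stop_sets, birdday, population, chl_birds) -> pd.DataFrame:
    rows = []
    # "mean moon" for the duration model: mean nightly illumination over
    # ALL nights of the migration window (stopover nights included) — the
    # moon exposure of the whole migration, not only of travelling nights
    mig_nights = birdday[birdday["phase"] == "night"]
    stop_days = birdday[birdday["is_stopover_day"]]
    for it in population:
        bid = it.bird_id
        if bid not in tracks:
            continue
        tr = tracks[bid]
        ss = stop_sets.get(bid)
        nights = mig_nights[mig_nights["bird_id"] == bid]
        sdays = stop_days[stop_days["bird_id"] == bid]
        stop_forage = (
            sdays.groupby("date")["forage_hours"].sum().mean()
            if not sdays.empty
            else np.nan
        )
        start = tr.migration_start
        dep_abs = (start - dt.date(start.year, 8, 1)).days
        lay_abs = (
            (it.lay_date - dt.date(it.lay_date.year, 4, 1)).days
            if it.lay_date is not None
            else np.nan
        )
        rows.append(
            {
                "bird_id": bid,
                "bird": bid.rsplit("_", 1)[0],
                "year": it.year,
                "colony": it.colony.name,
                "migration_start": start,
                "migration_end": tr.migration_end,
                "departure_abs": dep_abs,
                "departure": dep_abs,
                "duration_days": tr.duration_days,
                "n_stopovers": ss.n_stopovers if ss else 0,
                "total_stopover_days": ss.total_stopover_days if ss else 0,
                "mean_stopover_length": (
                    float(np.mean([s.length_days for s in ss.stopovers]))
                    if ss and ss.stopovers else np.nan
                ),
                "mean_gap_days": (
                    float(np.mean(ss.gaps_days))
                    if ss and len(ss.gaps_days) else np.nan
                ),
                "mean_moon": (
                    float(nights["moon_illumination"].mean())
                    if not nights.empty else np.nan
                ),
                "stopover_forage_hours": stop_forage,
                "lay": lay_abs,
                "lay_abs": lay_abs,
            }
        )
    birds = pd.DataFrame(rows)
    if chl_birds is not None:
        birds = birds.merge(chl_birds, on="bird_id", how="left")
    birds["dep_c"] = birds["departure_abs"] - birds["departure_abs"].mean()
    return birds


def summarise(birds: pd.DataFrame, stop_sets, maxcont: dict) -> pd.DataFrame:
    """Table-1-style summary: mean / min / max of the phenology and
    stopover metrics over the analysed birds."""
    lengths = [
        s.length_days for ss in stop_sets.values() for s in ss.stopovers
    ]
    gaps = [g for ss in stop_sets.values() for g in ss.gaps_days]
    cont = [maxcont[b] for b in birds["bird_id"] if b in maxcont]

    def row(name, vals):
        vals = np.asarray(
            [v for v in vals if v is not None and np.all(pd.notna(v))]
        )
        if len(vals) == 0:
            return {"metric": name, "mean": np.nan, "sd": np.nan,
                    "min": np.nan, "max": np.nan}
        return {
            "metric": name,
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            "min": float(np.min(vals)),
            "max": float(np.max(vals)),
        }

    start_doy = [
        (d - dt.date(d.year, 1, 1)).days + 1 for d in birds["migration_start"]
    ]
    end_doy = [
        (d - dt.date(d.year, 1, 1)).days + 1 for d in birds["migration_end"]
    ]
    return pd.DataFrame(
        [
            row("migration_start_doy", start_doy),
            row("migration_end_doy", end_doy),
            row("migration_duration_days", birds["duration_days"]),
            row("stopover_number", birds["n_stopovers"]),
            row("total_stopover_days", birds["total_stopover_days"]),
            row("stopover_length_days", lengths),
            row("time_between_stopovers_days", gaps),
            row("max_continuous_flight_h", cont),
        ]
    )


def _tables_hash(tables: dict) -> str:
    h = hashlib.sha256()
    for name in sorted(tables):
        t = tables[name]
        if t is None:
            continue
        h.update(name.encode())
        h.update(t.round(9).to_csv(index=False).encode())
    return h.hexdigest()[:16]


def _write_bundle(bundle: dict, out: Path):
    out.mkdir(parents=True, exist_ok=True)
    bundle["truth"].to_csv(out / "truth_birds.csv", index=False)
    bundle["birdday"].to_csv(out / "birdday.csv", index=False)
    bundle["birds"].to_csv(out / "birds.csv", index=False)
    bundle["summary"].to_csv(out / "summary.csv", index=False)
    bundle["exclusions"].to_csv(out / "exclusions.csv", index=False)
    bundle["model_report"]["table"].to_csv(out / "model_report.csv", index=False)
    pd.concat(
        [ss.to_frame() for ss in bundle["stopover_sets"].values()],
        ignore_index=True,
    ).to_csv(out / "stopovers.csv", index=False)
    mix = bundle["mixture"]
    (out / "mixture.txt").write_text(
        "\n".join(
            f"{k}={getattr(mix, k)}"
            for k in ("mean_low", "mean_high", "sd_low", "sd_high",
                      "weight_low", "log_likelihood", "iterations",
                      "converged")
        )
        + "\n"
    )
    (out / "manifest.json").write_text(json.dumps(bundle["manifest"], indent=2))
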