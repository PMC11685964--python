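"""Generator behaviour: phenology structure, sensor rendering, determinism."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from migrentic import astro, geolocate, synth


class TestSimulatePopulation:
    def test_lay_dates_within_configured_range(self, small_pop):
        for it in small_pop:
            assert it.lay_date is not None
            lo = dt.date(it.year, 4, 26)
            hi = dt.date(it.year, 6, 6)
            assert lo <= it.lay_date <= hi

    def test_zero_slope_zero_noise_gives_identical_departures(self):
        params = synth.PopulationParams(
            n_birds=6, seed=3, slope_departure_on_lay=0.0,
            departure_bird_sd=0.0, departure_noise_sd=0.0,
            years=(2015,),
        )
        pop = synth.simulate_population(params)
        deps = {it.departure_date for it in pop}
        assert len(deps) == 1
        assert deps.pop() == dt.date(2015, 9, 14)

    def test_departure_on_lay_slope_recovered_by_ols(self):
        pop = synth.simulate_population(
            synth.PopulationParams(n_birds=50, seed=1)
        )
        lay = [(p.lay_date - dt.date(p.year, 4, 1)).days for p in pop]
        dep = [(p.departure_date - dt.date(p.year, 8, 1)).days for p in pop]
        slope = stats.linregress(lay, dep).slope
        assert slope == pytest.approx(0.566, abs=0.05)

    def test_states_partition_days_and_order(self, bird):
        states = bird.days["state"]
        assert set(states) <= {"breeding", "migrating", "stopover", "wintering"}
        dep_idx = (bird.departure_date - bird.days["date"].iloc[0]).days
        assert all(s == "breeding" for s in states[:dep_idx])
        assert bird.departure_date > bird.lay_date

    def test_stopover_days_fly_less_than_migrating_days(self, bird):
        d = bird.days
        tot = d["day_flight_h"] + d["night_flight_h"]
        stop = tot[d["state"] == "stopover"].mean()
        mig = tot[d["state"] == "migrating"].mean()
        assert stop < mig - 3.0

    def test_night_flight_within_night_length(self, small_pop):
        for it in small_pop:
            d = it.days
            assert (d["night_flight_h"] >= 0).all()
            assert (d["night_flight_h"] <= d["night_length_h"] + 1e-9).all()

    def test_reproducible_given_seed(self, small_params, small_pop):
        again = synth.simulate_population(small_params)
        for a, b in zip(small_pop, again):
            pd.testing.assert_frame_equal(a.days, b.days)
            np.testing.assert_array_equal(a.bin_behaviour, b.bin_behaviour)
        # and rendered sensors are byte-identical too
        la = synth.render_light(small_pop[0]).to_frame().to_csv()
        lb = synth.render_light(again[0]).to_frame().to_csv()
        assert la == lb

    def test_infeasible_duration_slope_raises(self):
        with pytest.raises(synth.ParameterisationError):
            synth.PopulationParams(
                n_birds=5, seed=0, slope_duration_on_departure=-5.0
            ).__class__ and synth.simulate_population(
                synth.PopulationParams(
                    n_birds=5, seed=0, slope_duration_on_departure=-5.0
                )
            )

    def test_negative_sd_rejected(self):
        with pytest.raises(synth.ParameterisationError):
            synth.PopulationParams(residual_sd=-1.0)


class TestRenderLight:
    def test_equatorial_equinox_half_day_above_threshold(self):
        it = _fixed_position_itinerary(0.0, 0.0, dt.date(2015, 3, 16), 10)
        ls = synth.render_light(it)
        frac = np.mean(ls.light > ls.max_light / 2.0)
        assert frac == pytest.approx(0.5, abs=0.03)

    def test_twilight_roundtrip_matches_day_length(self):
        it = _fixed_position_itinerary(-5.0, 45.0, dt.date(2015, 7, 1), 6)
        ls = synth.render_light(it)
        cfg = geolocate.GeolocationConfig()
        tw = geolocate.detect_twilights(ls, cfg)
        pairs = [
            (a, b) for a, b in zip(tw, tw[1:])
            if a.event == "sunrise" and b.event == "sunset"
        ]
        for a, b in pairs[1:-1]:
            hours = (b.time - a.time).total_seconds() / 3600.0
            expect = astro.day_length(a.time.date(), 45.0, -4.5)
            assert hours == pytest.approx(expect, abs=10 / 60)

    def test_shading_events_rejected_by_twilight_filter(self):
        it = _fixed_position_itinerary(-5.0, 45.0, dt.date(2015, 7, 1), 30)
        clean = synth.render_light(it)
        shaded = synth.render_light(
            it, synth.LightNoise(shade_prob=0.2 / 144, seed=7)
        )
        assert np.sum(shaded.light < clean.light - 1) > 0  # events present
        cfg = geolocate.GeolocationConfig()
        n_clean = len(geolocate.detect_twilights(clean, cfg))
        n_shaded = len(geolocate.detect_twilights(shaded, cfg))
        assert abs(n_shaded - n_clean) <= 2


class TestRenderImmersion:
    def test_behaviour_score_mapping(self, bird, bird_immersion):
        scores = bird_immersion.wet.reshape(-1, 200).sum(axis=1)
        beh = bird.bin_behaviour
        assert scores[beh == synth.FLIGHT].max() == 0
        assert scores[beh == synth.REST].min() == 200
        forage = scores[beh == synth.FORAGE]
        assert forage.min() >= 1 and forage.max() <= 199

    def test_sample_interval_must_divide_bin(self, bird):
        with pytest.raises(ValueError):
            synth.render_immersion(bird, sample_seconds=7)

    def test_six_second_sampling_gives_hundred_per_bin(self, bird):
        im = synth.render_immersion(bird, sample_seconds=6, seed=1)
        scores = im.wet.reshape(-1, 100).sum(axis=1)
        assert scores[bird.bin_behaviour == synth.REST].min() == 100


class TestRenderChlGrid:
    dates = [dt.date(2015, 9, 1) + dt.timedelta(days=i) for i in range(4)]

    def test_uniform_field(self):
        g = synth.render_chl_grid(
            (-70, 0, -50, 56), self.dates,
            {"lat_coef": 0.0, "seasonal_decline": 0.0, "base": 1.0},
        )
        assert float(g.min()) == pytest.approx(1.0)
        assert float(g.max()) == pytest.approx(1.0)

    def test_values_nonnegative_with_gradient(self):
        g = synth.render_chl_grid((-70, 0, -50, 56), self.dates)
        assert float(g.min()) >= 0.0

    def test_missing_cells_masked_not_zeroed(self):
        g = synth.render_chl_grid(
            (-70, 0, -50, 56), self.dates,
            {"lat_coef": 0.0, "seasonal_decline": 0.0, "base": 1.0},
            seed=11, missing_fraction=0.3,
        )
        vals = g.values
        assert 0.2 < np.mean(np.isnan(vals)) < 0.4
        assert float(np.nanmean(vals)) == pytest.approx(1.0)

    def test_empty_extent_raises(self):
        with pytest.raises(ValueError):
            synth.render_chl_grid((-10, -20, 0, 10), self.dates)


def _fixed_position_itinerary(lon, lat, start, n_days):
    """Minimal stationary itinerary for light-rendering tests."""
    dates = [start + dt.timedelta(days=i) for i in range(n_days)]
    sunrise = np.empty(n_days, dtype="datetime64[s]")
    sunset = np.empty(n_days, dtype="datetime64[s]")
    nxt = np.empty(n_days, dtype="datetime64[s]")
    for k, d in enumerate(dates):
        r, s = astro.sun_events(d, lon, lat, "horizon")
        r2, _ = astro.sun_events(d + dt.timedelta(days=1), lon, lat, "horizon")
        sunrise[k] = np.datetime64(r.time.replace(tzinfo=None), "s")
        sunset[k] = np.datetime64(s.time.replace(tzinfo=None), "s")
        nxt[k] = np.datetime64(r2.time.replace(tzinfo=None), "s")
    days = pd.DataFrame(
        {
            "date": dates,
            "state": "breeding",
            "lon": lon,
            "lat": lat,
            "day_length_h": (sunset - sunrise).astype(float) / 3600.0,
            "night_length_h": (nxt - sunset).astype(float) / 3600.0,
            "night_illumination": 0.5,
            "sunrise": sunrise,
            "sunset": sunset,
            "next_sunrise": nxt,
            "day_flight_h": 0.0,
            "night_flight_h": 0.0,
            "day_forage_h": 0.0,
            "night_forage_h": 0.0,
        }
    )
    t0 = np.datetime64(dates[0], "s")
    bins = np.arange(
        t0, np.datetime64(dates[-1] + dt.timedelta(days=2), "s"),
        np.timedelta64(600, "s"),
    )
    return synth.TrueItinerary(
        bird_id="FIX", year=start.year, colony=synth.SKOMER,
        lay_date=None, departure_date=start, arrival_date=start,
        total_stopover_days=0, days=days, bin_times=bins,
        bin_behaviour=np.full(len(bins), synth.REST, dtype=np.int8),
        bin_date=np.zeros(len(bins), dtype=np.int64),
        bin_is_night=np.zeros(len(bins), dtype=bool),
    )
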