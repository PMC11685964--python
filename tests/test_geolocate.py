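"""Threshold geolocation: twilights, positions, calibration, phenology."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from migrentic import astro, geolocate, synth

UTC = dt.timezone.utc


class TestDetectTwilights:
    def test_alternating_events(self, bird_twilights):
        kinds = [e.event for e in bird_twilights]
        for a, b in zip(kinds, kinds[1:]):
            assert a != b

    def test_times_match_astro_prediction(self, bird, bird_light, geo_cfg):
        tw = geolocate.detect_twilights(bird_light, geo_cfg)
        # compare a mid-series sunrise against prediction at true position
        ev = [e for e in tw if e.event == "sunrise"][20]
        row = bird.days[bird.days["date"] == ev.time.date()].iloc[0]
        pred, _ = astro.sun_events(ev.time.date(), row.lon, row.lat, -4.5)
        assert abs((ev.time - pred.time).total_seconds()) < 600

    def test_injected_midday_shading_rejected(self):
        times = np.arange(
            np.datetime64("2015-07-01", "s"), np.datetime64("2015-07-04", "s"),
            np.timedelta64(600, "s"),
        )
        alt = np.asarray(astro.sun_altitude(times, 0.0, 45.0))
        light = 64.0 / (1 + np.exp(-(alt + 4.5)))
        cfg = geolocate.GeolocationConfig()
        clean = synth.LightSeries("x", times, light.copy())
        n_clean = len(geolocate.detect_twilights(clean, cfg))
        # 30-min dark event around midday of day 2
        noon_idx = np.argmin(np.abs(times - np.datetime64("2015-07-02T12:00")))
        light[noon_idx : noon_idx + 3] = 0.5
        shaded = synth.LightSeries("x", times, light)
        assert len(geolocate.detect_twilights(shaded, cfg)) == n_clean

    def test_constant_dark_day_yields_no_events(self):
        times = np.arange(
            np.datetime64("2015-07-01", "s"), np.datetime64("2015-07-03", "s"),
            np.timedelta64(600, "s"),
        )
        series = synth.LightSeries("x", times, np.zeros(len(times)))
        assert geolocate.detect_twilights(
            series, geolocate.GeolocationConfig()
        ) == []

    def test_too_short_series_raises(self):
        times = np.arange(
            np.datetime64("2015-07-01", "s"), np.datetime64("2015-07-01T06:00", "s"),
            np.timedelta64(600, "s"),
        )
        with pytest.raises(ValueError):
            geolocate.detect_twilights(
                synth.LightSeries("x", times, np.ones(len(times))),
                geolocate.GeolocationConfig(),
            )


class TestEstimatePosition:
    def test_noon_at_1200_utc_is_greenwich(self):
        # Sep 1: equation of time ~ 0
        sunrise = dt.datetime(2015, 9, 1, 6, 0, tzinfo=UTC)
        sunset = dt.datetime(2015, 9, 1, 18, 0, tzinfo=UTC)
        lon, lat, eq = geolocate.estimate_position(
            sunrise, sunset, dt.date(2015, 9, 1), -4.5
        )
        assert lon == pytest.approx(0.0, abs=0.6)

    def test_late_noon_gives_west_longitude(self):
        # midpoint 15:26 UTC -> (12 - 15.433) * 15 = -51.5 deg (EoT ~ 0)
        sunrise = dt.datetime(2015, 9, 1, 9, 26, tzinfo=UTC)
        sunset = dt.datetime(2015, 9, 1, 21, 26, tzinfo=UTC)
        lon, _, _ = geolocate.estimate_position(
            sunrise, sunset, dt.date(2015, 9, 1), -4.5
        )
        assert lon == pytest.approx(-51.5, abs=0.6)

    def test_equinox_latitude_masked(self):
        sunrise = dt.datetime(2015, 9, 22, 6, 0, tzinfo=UTC)
        sunset = dt.datetime(2015, 9, 22, 18, 0, tzinfo=UTC)
        lon, lat, eq = geolocate.estimate_position(
            sunrise, sunset, dt.date(2015, 9, 22), -4.5
        )
        assert eq is True
        assert lat is None

    def test_inverted_ordering_raises(self):
        t1 = dt.datetime(2015, 9, 1, 18, 0, tzinfo=UTC)
        t0 = dt.datetime(2015, 9, 1, 6, 0, tzinfo=UTC)
        with pytest.raises(ValueError):
            geolocate.estimate_position(t1, t0, dt.date(2015, 9, 1), -4.5)


class TestRoundTrip:
    @staticmethod
    def _truth_at_epoch(truth, pos, col):
        # midnight (night-half) estimates straddle two daily positions
        out = []
        for d, half in zip(pos["date"], pos["half"]):
            nxt = d + dt.timedelta(days=1)
            if half == "night" and nxt in truth.index:
                out.append((truth.loc[d, col] + truth.loc[nxt, col]) / 2)
            else:
                out.append(truth.loc[d, col])
        return np.array(out)

    def test_position_recovery_on_noise_free_track(self, bird, bird_track):
        truth = bird.days.set_index("date")
        pos = bird_track.positions
        tl = self._truth_at_epoch(truth, pos, "lon")
        ta = self._truth_at_epoch(truth, pos, "lat")
        lon_rmse = np.sqrt(np.nanmean((pos["lon"] - tl) ** 2))
        assert lon_rmse <= 0.5
        ok = (~pos["equinox_flag"]) & np.isfinite(pos["lat"])
        lat_rmse = np.sqrt(np.mean((pos["lat"][ok] - ta[ok]) ** 2))
        assert lat_rmse <= 2.0

    def test_longitude_error_no_equinox_inflation(self, bird, bird_track):
        truth = bird.days.set_index("date")
        pos = bird_track.positions
        err = np.abs(
            pos["lon"].to_numpy() - self._truth_at_epoch(truth, pos, "lon")
        )
        inside = pos["equinox_flag"].to_numpy()
        rmse_in = np.sqrt(np.mean(err[inside] ** 2))
        rmse_out = np.sqrt(np.mean(err[~inside] ** 2))
        assert rmse_in <= max(2.0 * rmse_out, 0.5)

    def test_latitude_absent_inside_equinox_window(self, bird_track):
        inside = bird_track.positions["equinox_flag"]
        assert bird_track.positions.loc[inside, "lat"].isna().all()


class TestCalibration:
    def test_recovers_generating_elevation(self, bird, bird_light):
        elev = geolocate.calibrate_sun_elevation(
            bird_light, bird.colony.lat, bird.departure_date,
        )
        assert elev == pytest.approx(-4.5, abs=0.5)

    def test_deterministic_across_identical_birds(self, bird, bird_light):
        e1 = geolocate.calibrate_sun_elevation(
            bird_light, bird.colony.lat, bird.departure_date
        )
        e2 = geolocate.calibrate_sun_elevation(
            bird_light, bird.colony.lat, bird.departure_date
        )
        assert e1 == e2

    def test_range_containing_truth_beats_disjoint_range(self, bird, bird_light):
        good = geolocate.calibrate_sun_elevation(
            bird_light, bird.colony.lat, bird.departure_date,
            candidate_range=np.arange(-5.5, -3.4, 0.25),
        )
        bad = geolocate.calibrate_sun_elevation(
            bird_light, bird.colony.lat, bird.departure_date,
            candidate_range=np.arange(-2.0, -0.9, 0.25),
        )
        assert abs(good - (-4.5)) < abs(bad - (-4.5))


class TestMigrationWindow:
    def test_detected_start_near_truth(self, bird, bird_track):
        assert bird_track.migration_start is not None
        assert abs((bird_track.migration_start - bird.departure_date).days) <= 2

    def test_stationary_bird_flagged_incomplete(self):
        dates = pd.date_range("2015-08-01", "2015-12-01").date
        lon = pd.Series(-5.3 + 0.01 * np.sin(np.arange(len(dates))), index=dates)
        track = geolocate.PositionTrack(
            "still", pd.DataFrame({"date": dates, "half": "day",
                                   "lon": lon.values, "lat": 51.7,
                                   "equinox_flag": False}),
            lon, lon,
        )
        geolocate.detect_migration_window(track, geolocate.GeolocationConfig())
        assert track.incomplete

    def test_invariant_to_prepending_preaugust_data(self, bird, bird_light, geo_cfg):
        tw = geolocate.detect_twilights(bird_light, geo_cfg)
        full = geolocate.build_track(bird.bird_id, tw, geo_cfg)
        aug = dt.date(bird.year, 8, 1)
        tw_late = [e for e in tw if e.time.date() >= aug]
        late = geolocate.build_track(bird.bird_id, tw_late, geo_cfg)
        assert full.migration_start == late.migration_start
        assert full.migration_end == late.migration_end

    def test_long_stopover_still_reaches_end(self):
        # one 22-day stopover mid-route: end must still be detected and the
        # duration includes the stopover days
        params = synth.PopulationParams(
            n_birds=1, seed=12, years=(2015,),
            stopover_days_base=22.0, stopover_days_noise_sd=0.0,
            stopover_block_mean_days=22.0, duration_base=40.0,
            duration_noise_sd=0.0, duration_moon_effect=0.0,
        )
        it = synth.simulate_population(params)[0]
        cfg = geolocate.GeolocationConfig()
        track = geolocate.build_track(
            it.bird_id,
            geolocate.detect_twilights(synth.render_light(it), cfg), cfg,
        )
        assert not track.incomplete
        assert track.duration_days >= 22


class TestSmoothing:
    def test_constant_series_unchanged(self):
        dates = pd.date_range("2015-08-01", "2015-08-20").date
        lon = pd.Series(-5.0, index=dates)
        sm = lon.rolling(3, center=True, min_periods=1).mean()
        pd.testing.assert_series_equal(sm, lon, check_names=False)
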