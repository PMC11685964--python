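"""Mixed-model machinery: fits, LRTs, bootstrap CIs, ICCs, the suite."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from migrentic import models, synth


def _df(n=60, seed=1, beta=2.0, bird_sd=0.5, resid=1.0, n_birds=12):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n)
    bird = np.repeat(np.arange(n_birds), n // n_birds)
    y = 1.0 + beta * x + rng.normal(0, bird_sd, n_birds)[bird]
    y = y + rng.normal(0, resid, n)
    return pd.DataFrame(
        dict(y=y, x=x, bird=bird.astype(str), year="2014")
    )


class TestFitLmm:
    def test_zero_noise_recovers_slope_exactly(self):
        df = _df(bird_sd=0.0, resid=0.0)
        fit = models.fit_lmm("y ~ x", df)
        assert fit.params["x"] == pytest.approx(2.0, abs=1e-8)
        assert all(v <= 1e-6 for v in fit.vcomp.values())
        assert fit.resid_var <= 1e-10

    def test_matches_ols_when_random_variance_zero(self):
        df = _df(bird_sd=0.0, resid=1.0, seed=4)
        mixed = models.fit_lmm("y ~ x", df, groups=("bird",))
        import statsmodels.api as sm

        ols = sm.OLS.from_formula("y ~ x", df).fit()
        assert mixed.params["x"] == pytest.approx(ols.params["x"], abs=0.02)

    def test_single_level_grouping_dropped_with_warning(self):
        df = _df()
        fit = models.fit_lmm("y ~ x", df, groups=("bird", "year"))
        assert fit.groups_used == ("bird",)
        assert any("year" in w for w in fit.warnings)

    def test_no_groupings_degenerates_to_ols(self):
        df = _df().assign(bird="only", year="2014")
        fit = models.fit_lmm("y ~ x", df)
        assert fit.groups_used == ()
        assert np.isfinite(fit.loglik)


class TestLrt:
    def test_identical_models_give_zero_statistic(self):
        df = _df()
        fit = models.fit_lmm("y ~ x", df)
        chi2, dof, p = models.lrt(fit, fit)
        assert chi2 == 0.0 and p == 1.0

    def test_statistic_matches_direct_likelihood_evaluation(self):
        # 20-row worked dataset, no random structure: both logliks can be
        # recomputed from the gaussian density at the ML estimates
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 20)
        y = 0.5 + 1.5 * x + rng.normal(0, 1, 20)
        df = pd.DataFrame(dict(y=y, x=x, bird="b", year="y"))
        full = models.fit_lmm("y ~ x", df)
        red = models.fit_lmm("y ~ 1", df)

        def loglik(resid):
            s2 = np.mean(resid**2)
            return float(np.sum(stats.norm.logpdf(resid, 0, np.sqrt(s2))))

        ll_full = loglik(y - (full.params["Intercept"] + full.params["x"] * x))
        ll_red = loglik(y - red.params["Intercept"])
        chi2, dof, p = models.lrt(full, red)
        assert chi2 == pytest.approx(2 * (ll_full - ll_red), abs=1e-6)
        assert dof == 1
        assert 0 < p <= 1

    def test_non_nested_rejected(self):
        df = _df()
        a = models.fit_lmm("y ~ x", df)
        b = models.fit_lmm("y ~ x", df.iloc[:30])
        with pytest.raises(ValueError):
            models.lrt(a, b)


class TestBootstrapCI:
    def test_same_seed_identical(self):
        fit = models.fit_lmm("y ~ x", _df())
        a = models.bootstrap_ci(fit, 200, seed=9)
        b = models.bootstrap_ci(fit, 200, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_noise_interval_collapses(self):
        fit = models.fit_lmm("y ~ x", _df(bird_sd=0.0, resid=0.0))
        ci = models.bootstrap_ci(fit, 200, seed=1)
        width = ci["ci_hi"] - ci["ci_lo"]
        assert (width < 1e-4).all()

    def test_interval_contains_point_estimate(self):
        fit = models.fit_lmm("y ~ x", _df(seed=7))
        ci = models.bootstrap_ci(fit, 1000, seed=2)
        assert (ci["ci_lo"] <= ci["estimate"]).all()
        assert (ci["estimate"] <= ci["ci_hi"]).all()


class TestIcc:
    def _fit(self, vcomp, resid):
        return models.ModelFit(
            model_id=0, formula="", params=pd.Series(dtype=float),
            cov_params=pd.DataFrame(), loglik=0.0, n_obs=10, n_fixed=1,
            vcomp=vcomp, resid_var=resid, converged=True, singular=False,
            groups_used=tuple(vcomp),
        )

    def test_zero_variance_gives_zero(self):
        assert models.icc(self._fit({"year": 0.0, "bird": 2.0}, 7.0), "year") == 0.0

    def test_arithmetic(self):
        fit = self._fit({"bird": 2.0, "year": 1.0}, 7.0)
        assert models.icc(fit, "bird") == pytest.approx(0.2)

    def test_shares_sum_to_one_with_residual(self):
        fit = self._fit({"bird": 2.0, "year": 1.0}, 7.0)
        shares = (
            models.icc(fit, "bird")
            + models.icc(fit, "year")
            + fit.resid_var / (sum(fit.vcomp.values()) + fit.resid_var)
        )
        assert shares == pytest.approx(1.0)


class TestModelRecovery:
    def test_moon_effect_recovered_from_generated_nights(self):
        # model-2 structure straight from the generating equation
        rng = np.random.default_rng(5)
        nb, nn = 60, 30
        bird = np.repeat(np.arange(nb), nn)
        year = (bird % 3).astype(str)
        moon = rng.uniform(0, 1, nb * nn)
        dep_c = np.repeat(rng.normal(0, 7, nb), nn)
        y = (
            2.106 + 3.245 * moon + 0.015 * dep_c + 0.018 * moon * dep_c
            + rng.normal(0, 0.5, nb)[bird]
            + rng.normal(0, 1.5, nb * nn)
        )
        df = pd.DataFrame(
            dict(y=y, moon=moon, dep_c=dep_c, bird=bird.astype(str), year=year)
        )
        fit = models.fit_lmm("y ~ moon + dep_c + moon:dep_c", df)
        assert fit.params["moon"] == pytest.approx(3.245, rel=0.10)

    def test_breeding_period_slope_is_departure_slope_minus_one(self, small_pop):
        pop = synth.simulate_population(
            synth.PopulationParams(n_birds=60, seed=6)
        )
        lay = np.array([(p.lay_date - dt.date(p.year, 4, 1)).days for p in pop])
        dep = np.array([(p.departure_date - dt.date(p.year, 8, 1)).days for p in pop])
        breeding = (dep + 122) - lay  # days between lay and departure
        s_dep = stats.linregress(lay, dep).slope
        s_breed = stats.linregress(lay, breeding).slope
        assert s_breed == pytest.approx(s_dep - 1.0, abs=1e-9)


@pytest.fixture(scope="module")
def suite_tables():
    rng = np.random.default_rng(8)
    nb, nn = 30, 12
    bird = np.repeat([f"b{i}" for i in range(nb)], 2 * nn)
    colony = np.repeat(
        [synth.DEFAULT_COLONIES[i % 5].name for i in range(nb)], 2 * nn
    )
    year = np.repeat([str(2014 + i % 3) for i in range(nb)], 2 * nn)
    phase = np.tile(["day", "night"], nb * nn)
    moon = rng.uniform(0, 1, 2 * nb * nn)
    dep = np.repeat(rng.normal(44, 6, nb), 2 * nn)
    flight = np.where(
        phase == "day", rng.normal(7, 1.5, 2 * nb * nn),
        2 + 3.2 * moon + rng.normal(0, 1.5, 2 * nb * nn),
    ).clip(0)
    dates = np.tile(
        np.repeat(
            [dt.date(2014, 9, 10) + dt.timedelta(days=i) for i in range(nn)], 2
        ),
        nb,
    )
    birdday = pd.DataFrame(
        {
            "bird_id": bird, "bird": bird, "year": year, "colony": colony,
            "date": dates, "phase": phase, "flight_hours": flight,
            "forage_hours": rng.uniform(0, 6, 2 * nb * nn),
            "phase_length_h": 12.0,
            "flight_proportion": flight / 12.0,
            "moon_illumination": np.where(phase == "night", moon, np.nan),
            "moon_up_fraction": np.where(
                phase == "night", rng.uniform(0, 1, 2 * nb * nn), np.nan
            ),
            "is_stopover_day": False,
            "departure_abs": dep,
        }
    )
    birdday["dep_c"] = birdday["departure_abs"] - birdday["departure_abs"].mean()
    b = rng
    birds = pd.DataFrame(
        {
            "bird_id": [f"b{i}" for i in range(nb)],
            "bird": [f"b{i}" for i in range(nb)],
            "year": [str(2014 + i % 3) for i in range(nb)],
            "colony": [synth.DEFAULT_COLONIES[i % 5].name for i in range(nb)],
            "departure": rng.normal(44, 6, nb),
            "departure_abs": rng.normal(44, 6, nb),
            "duration_days": rng.normal(31, 4, nb),
            "total_stopover_days": rng.integers(1, 20, nb).astype(float),
            "mean_moon": rng.uniform(0.3, 0.7, nb),
            "stopover_forage_hours": rng.normal(12, 1, nb),
            "mean_chl_ratio": rng.uniform(0.2, 0.6, nb),
            "lay": rng.uniform(25, 66, nb),
        }
    )
    birds["lay_abs"] = birds["lay"]
    birds["dep_c"] = birds["departure_abs"] - birds["departure_abs"].mean()
    return {"birdday": birdday, "birds": birds}

    def test_all_ten_models_reported(self, suite_tables):
        out = models.run_model_suite(suite_tables, n_boot=100, seed=1, do_lrt=False)
        assert set(out["fits"]) == set(range(1, 11))
        assert out["skipped"] == {}
        t = out["table"]
        assert set(t["model_id"]) == set(range(1, 11))
        assert {"estimate", "ci_lo", "ci_hi"} <= set(t.columns)

    def test_lrt_columns_populated_for_tested_terms(self, suite_tables):
        out = models.run_model_suite(
            {"birdday": suite_tables["birdday"], "birds": None},
            n_boot=50, seed=2, do_lrt=True,
        )
        t = out["table"]
        moon_row = t[(t["model_id"] == 2) & (t["term"] == "moon")].iloc[0]
        assert moon_row["chisq"] >= 0
        assert 0 < moon_row["p"] <= 1
        assert 5 in out["skipped"]

    def test_missing_tables_skipped_with_reason(self):
        out = models.run_model_suite({"birdday": None, "birds": None})
        assert len(out["skipped"]) == 10
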