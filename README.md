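# migrentic

Geolocator-based analysis of seabird autumn migration, built around the
Manx shearwater (*Puffinus puffinus*) system: birds breeding around the
British Isles that migrate trans-equatorially to the Patagonian shelf.
The package is for movement ecologists who want a tested, reusable
implementation of the standard GLS (global location sensing) analysis
chain — and a synthetic-data generator with complete ground truth to
validate every step of it.

## What it does

1. **Simulate** populations of migrating birds (`migrentic.synth`) whose
   phenology follows the effect structure estimated for this system: departure date
   responds to lay date (β = 0.566 d/d), later departures mean fewer
   stopover days (β = −0.156) and shorter migrations (β = −0.323 d/d),
   nightly flight increases with moon illumination (β = 3.245 h per unit
   illuminated fraction). Raw light and wet/dry immersion streams are
   rendered from the true positions and behaviours.
2. **Geolocate** by the threshold method (`migrentic.geolocate`):
   twilights from light-threshold crossings, longitude from the timing of
   local noon/midnight via the equation of time, latitude from inverting
   day length at a calibrated sun elevation (default −4.5°), with
   latitude masked ±15 days around the equinoxes. Migration start/end
   from sustained westward change of the 3-day-smoothed longitude.
3. **Classify activity** (`migrentic.immersion`): 10-min immersion
   scores 0–200; 0 = flight, 1–199 = foraging, 200 = resting on the
   water; per bird-day/night flight and foraging hours with moon
   covariates.
4. **Detect stopovers** (`migrentic.stopover`): a two-component normal
   mixture over daily flight hours fitted by EM; days with posterior
   > 0.66 for the low-flight component are stopover days.
5. **Compute chlorophyll ratios** (`migrentic.enviro`): mean
   chlorophyll-a in a 0.08° box at each stopover centroid over the
   wintering-box mean (36–46° S, 54–66° W) on the same dates.
6. **Fit the model suite** (`migrentic.models`): ten Gaussian linear
   mixed models (ML) with crossed random intercepts for bird and year,
   likelihood-ratio tests (χ² = 2Δlogℒ), parametric bootstrap 95% CIs
   (1000 draws), and intra-class correlations.

`migrentic.astro` supplies the self-contained solar/lunar ephemeris
(sun altitude, day length, twilight times, moon illuminated fraction,
moon rise/set) used throughout; `migrentic.pipeline` orchestrates the
whole chain with QC filtering and a reproducibility manifest.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

```python
from migrentic import pipeline, synth

cfg = pipeline.RunConfig(
    params=synth.PopulationParams(n_birds=20, seed=42),
    seed=42, n_boot=500, do_lrt=False,
)
bundle = pipeline.run_all(cfg)
print(bundle["summary"][["metric", "mean", "min", "max"]].to_string(index=False))

fit = bundle["model_report"]["fits"][2]   # night flight ~ moon + departure
print(f"moon effect: {fit.params['moon']:.2f} h per unit illumination")
```

Output from this exact run:

```
                     metric     mean   min        max
        migration_start_doy 255.3500 243.0 271.000000
          migration_end_doy 285.2000 278.0 296.000000
    migration_duration_days  29.8500  25.0  35.000000
            stopover_number   5.0000   1.0   9.000000
        total_stopover_days  10.3000   8.0  13.000000
       stopover_length_days   2.0600   1.0   9.000000
time_between_stopovers_days   2.7375   1.0  10.000000
    max_continuous_flight_h  10.4500   8.5  12.333333
moon effect: 3.02 h per unit illumination
```

Mean detected migration start is day-of-year 255 (mid September), mean
duration ~30 days with ~10 stopover days — the generating conditions —
and the fitted moon effect (truth 3.245 h) is recovered within its
sampling error at 20 birds. The CLI exposes the same steps
(`migrentic generate`, `migrentic run-all`, `migrentic moontable`, ...).

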