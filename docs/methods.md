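# Methods

`migrentic` re-implements, as a tested pipeline, the analysis chain used to
study autumn migration of Manx shearwaters (*Puffinus puffinus*) from
combined light/immersion geolocators: light-threshold geolocation,
wet/dry activity classification, mixture-model stopover detection, lunar
and chlorophyll covariates, and a suite of ten Gaussian linear
mixed-effects models linking breeding phenology to migratory behaviour.
Because real deployments are not bundled, every stage is validated
against a synthetic-data generator with complete ground truth.

## The synthetic population generator

Each simulated bird-year carries a lay date, a departure date, an
itinerary (breeding → migrating/stopover → wintering), per-day positions
on a great circle from the colony to the centre of the Patagonian-shelf
wintering box (41° S, 60° W), per-day flight/forage hours split between
daylight and night, and 10-minute behavioural bins from which the raw
sensor streams are rendered.

Generating equations (defaults in parentheses; covariates on the model
scales — departure as days since 1 August centred on the population mean
departure of 14 September, lay as days since 1 April, moon as illuminated
fraction 0–1):

- lay ~ Uniform(26 April, 6 June); departure = 14 Sep +
  0.566 · (lay − mean lay) + bird effect (sd 2.0 d) + noise (sd 1.5 d);
- total stopover days = 10.07 − 0.156 · departure + noise (sd 0.5 d),
  floored at 1; stopover blocks have geometric lengths (mean 2.69 d) and
  are separated by at least one travel day, with ≥ 5 travel days before
  the first block and ≥ 3 after the last (shearwaters travel for several
  days before the first refuelling stop; the margins also keep the
  phenology endpoints identifiable);
- migration duration = 31.72 − 0.323 · departure − 15.633 ·
  (mean night illumination − 0.5) + noise (sd 0.8 d), floored at
  stopovers + 10 travel days; the moon exposure is the mean illuminated
  fraction at local solar midnight over the nights of the expected
  window given departure, evaluated along an approximate route (the
  illuminated fraction is a global quantity; position only shifts the
  midnight instant by a few hours).  Defining the exposure over an
  (essentially) exogenous window matters: a window that itself responds
  to the moon effect makes the covariate endogenous and biases recovery;
- on migrating nights, flight hours = 2.106 + 3.245 · moon +
  0.015 · departure + 0.018 · moon · departure + bird RE (sd 0.5 h) +
  year RE (sd 0.2 h) + residual (sd 1.5 h), truncated to [0, night
  length]; night foraging = 6.134 − 2.846 · moon + residual;
- on migrating days (daylight), flight = (2.106 + ½·3.245 + 3.827) +
  0.001 · departure + REs + residual, so the day−night contrast at the
  long-run mean illumination of 0.5 equals the configured −3.827 h;
- stopover (and breeding/wintering) days draw low daily flight totals
  from N(3.0, 1.0) h and forage-heavy budgets (12.556 + 0.010 ·
  departure h/day).

Two generating conventions deserve emphasis.  First, the departure
covariate is centred, in the generator and in the fitted models, so the
moon main effect is the effect at an average departure date; with an
uncentred moon × departure interaction that coefficient would be an
extrapolation to 1 August and nearly unidentifiable.  Second, the
slopes of the day/night contrast model (model 1) are *implied* by the
moon-driven night equation and the day equation: its true night effect is
−3.827 + 3.245 · (mean illumination − 0.5) and its true night × departure
slope is (0.015 + 0.018 · mean illumination) − 0.001.  Recovery tests
compare against these implied values, computed from the realised mean
illumination.

Residual scales are deliberately modest compared to field data (where
departure dates scatter by more than a week around the lay-date trend).
The generator is a validation instrument: with modest noise, a failed
recovery test indicates an implementation defect rather than sampling
noise, at populations of 60–90 birds.  Consequences: passing tests
demonstrate correctness of the machinery under the assumed generating
structure, not statistical power on real data.

Other non-realisms, by design: great-circle trajectories with constant
daily displacement (no wind drift, no coastline avoidance); noise-free
immersion (wet/dry conduction is treated as perfect, so behavioural
classification is exact by construction); light shading events are
optional and off by default; the immersion sampling interval defaults to
3 s so the 10-min summed score spans 0–200 exactly (a 6 s interval, which
yields 100 samples per bin, is supported and the score is rescaled to the
0–200 range).

## Astronomy

Self-contained analytic ephemerides: truncated series for solar position
(~0.01° accuracy) and the short low-precision lunar series (~0.3° in
longitude).  Illuminated fraction comes from the phase angle with finite
solar distance; rise/set from 2-minute scanning of topocentric altitude
with linear refinement, using the standard rise/set altitude of +0.125°
for the moon and −0.833° for the sun.  This is amply sufficient here:
geolocation position error (tens of km) dominates ephemeris error, and
illuminated fraction / rise-set accuracy is verified in the tests against
eclipse instants and an independent, fuller lunar series (±0.02 fraction,
±15 min).  The per-night moon covariate is the illuminated fraction at
local solar midnight; the moon-up covariate is the fraction of 10-min
night bins with the moon above the rise/set altitude.  Supported epoch
1990–2050.

## Geolocation

Twilights are interpolated threshold crossings of the light curve.  Dark
or light spells shorter than 4 h are treated as shading artifacts and
merged away; this removes a mid-day shading event without disturbing the
surrounding twilight pair.  Positions are bi-daily: local apparent noon
(midpoint of sunrise→sunset) and midnight (sunset→next sunrise) give
longitude via the equation of time at 15°/h; latitude inverts the
day-length equation at the calibrated sun elevation (−4.5° by default)
in closed form.  Latitude is masked within ±15 days of each equinox,
where day length is ~12 h at every latitude; longitude is unaffected,
which is why phenology uses the longitude series smoothed with a centred
3-day rolling mean.

Migration start/end is an automated rule in place of visual inspection:
start at the first run of ≥ 5 consecutive days of westward smoothed-
longitude change ≥ 0.5°/day, shifted by a calibrated 2-day lag (centred
smoothing plus midday positioning make the first detectable change
precede the true departure by two days on synthetic tracks); end at the
first ≥ 3-day spell with smoothed longitude inside the wintering band
[−66°, −54°], shifted by a calibrated 3-day lag (the band-entry rule
fires when the bird crosses into the band, about three days before it
reaches the box centre; without the lag, detected durations carry a
constant −3 day offset and, more damagingly, the migration window used
for the mean-moon covariate is misaligned).  Birds without a detected
start or end are
excluded (incomplete migrations), mirroring the QC step of the original
processing.

Calibration of the sun elevation angle scans a candidate range and picks
the elevation minimising the median absolute latitude error against the
colony latitude over pre-departure days — the latitude-against-colony
procedure used in the field, made explicit.

## Activity classification and the bird-day table

Wet/dry samples are summed into UTC-aligned 10-min scores scaled to
0–200.  Score 0 = flight, 1–199 = foraging, 200 = resting on the water.
The bird-day for date *d* spans sunrise(*d*) to sunrise(*d*+1); bins
straddling a twilight are split pro-rata (the original analysis does not
state its convention; pro-rata is ours).  Flight/forage hours per phase
are bin counts divided by six; "continuous flight" is the longest run of
consecutive fully-dry bins, allowed to cross midnight.  Missing bins are
excluded from both the sums and the phase length, never imputed.

## Stopover detection

Daily whole-day flight-hour totals for all bird-days inside the detected
migration window (one pooled model across birds, as in the source
analysis; whether pre-departure days entered the original pooled fit is
unstated — we restrict to the migration window) are fitted with a
two-component normal mixture by EM.  Initialisation is deterministic
(means at the 25th/75th percentiles, sds at half the pooled sd, weight
0.5) plus four seeded jittered restarts; components are labelled by mean
order; the log-likelihood is asserted non-decreasing at every iteration.
A bird-day is a stopover day when the posterior of the low-flight
component strictly exceeds 0.66.  Consecutive flagged days form
stopovers; centroids average the smoothed longitude and the
equinox-masked latitudes over the stopover's days.

## Chlorophyll ratios

For each stopover, mean chlorophyll-a over a square box of half-width
0.08° around the centroid over the stopover's dates, divided by the mean
over the wintering box (36–46° S, 54–66° W) on the same dates.  The
wintering-box mean is cos-latitude weighted (10° of latitude span); the
tiny stopover box is not; both switches are configurable, and a box
narrower than the grid spacing falls back to the nearest cell.  Missing
(cloud-masked) cells are excluded from the means.  Stopovers whose
centroid latitude is undefined (all days equinox-masked) report a missing
ratio rather than a guessed one.  The synthetic grid has an exponential
latitudinal gradient plus a seasonal decline applied to northern
cells, which reproduces the qualitative decline of stopover productivity
with later departure.

## The model suite

All ten models are Gaussian LMMs fitted by maximum likelihood with
crossed random intercepts for bird and year (implemented as variance
components over one trivial group).  Groupings with fewer than two
levels are dropped with a warning; with none left the fit is the exact
OLS limit.  Singular variance estimates are kept at the boundary and
flagged, not refitted.  Colony enters as a fixed factor (reference level
Copeland) whenever more than one colony is present.  Likelihood-ratio
tests drop one term at a time (the whole factor for colony) and compare
2Δlog-likelihood to the χ² distribution.  Confidence intervals are
parametric-bootstrap percentiles from draws of N(β̂, Côv(β̂)) — the
"resample model effects" flavour, not case resampling — 1000 draws,
seeded.  ICC for a grouping is its variance over the total random plus
residual variance.  No multiple-testing correction is applied.

## Numerical and testing choices

- Problem sizes: the acceptance suite runs one end-to-end population of
  60 birds; the acceptance script uses 80 (moon model) and 89 (lay-date
  model) birds, matching the field sample size for lay dates.
- Recovery criterion: an estimate within 10% of its generating value, or
  the generating value inside the 95% bootstrap CI — small generating
  coefficients (e.g. 0.001 h/day) are not identifiable to ±10% at these
  sample sizes, and the CI criterion is the calibrated statement of
  successful recovery.
- LRT calibration is checked under a simulated null (1000 datasets,
  n = 200, no random structure — the OLS limit of the same fitting code);
  bootstrap coverage over 200 mixed datasets of 30 birds × 8 obs.
- EM tolerance 1e-8 on the log-likelihood, max 500 iterations; mixture
  sds floored at 1e-3 to avoid variance collapse.
- Timestamps are UTC throughout; bird-day boundaries follow the detected
  (or predicted) twilights, not the clock.
- Determinism: every stochastic step takes a seed; identical configs give
  byte-identical output tables (hashed in the run manifest).

## Known limitations

- The generator's immersion stream is noise-free; classification accuracy
  on it is 100% by construction and says nothing about sensor noise or
  device heterogeneity (the original study restricted to 2007–2016
  devices; here a per-series `usable` flag is the caller's
  responsibility).
- Latitude error on real geolocator data (weather shading, behaviour) is
  far larger than on rendered light; the round-trip bounds (longitude
  RMSE ≤ 0.5°) characterise the estimator, not field accuracy.
- The mean-moon covariate of the duration model has very low
  between-bird variance (illumination averaged over a ~30-day window is
  close to the cycle mean of 0.5), so its coefficient is intrinsically
  weakly identified at n ≈ 60–100 — visible in its wide bootstrap CI,
  here as in the field data.
- No wind/storm covariates, no probabilistic geolocation, no k > 2
  mixtures, no GLMMs.
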