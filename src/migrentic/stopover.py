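"""Stopover detection via a two-component normal mixture fitted by EM.

Daily flight-hour totals pooled over all bird-days are modelled as a
mixture of a low-flight (stopover) and a high-flight (travelling)
component.  A bird-day is flagged as a stopover when its posterior
probability of the low component strictly exceeds the threshold (default
0.66).  Runs of consecutive flagged days form stopover segments with
lengths, gaps and positional centroids.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StopoverConfig",
    "MixtureFit",
    "Stopover",
    "StopoverSet",
    "fit_mixture_em",
    "assign_stopover_days",
    "segment_stopovers",
    "daily_flight_totals",
]


@dataclass(frozen=True)
class StopoverConfig:
    posterior_threshold: float = 0.66  # strict >
    max_iter: int = 500
    tol: float = 1e-8  # absolute log-likelihood change
    n_random_starts: int = 5
    seed: int = 0

    def __post_init__(self):
        if not (0.5 < self.posterior_threshold < 1.0):
            raise ValueError("posterior_threshold must be in (0.5, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class MixtureFit:
    mean_low: float
    mean_high: float
    sd_low: float
    sd_high: float
    weight_low: float
    log_likelihood: float
    iterations: int
    converged: bool
    loglik_trace: np.ndarray = field(repr=False, default=None)

    def posterior_low(self, x):
        """Responsibility of the low-flight component for value(s) x."""
        x = np.asarray(x, dtype=float)
        lo = self.weight_low * stats.norm.pdf(x, self.mean_low, self.sd_low)
        hi = (1 - self.weight_low) * stats.norm.pdf(x, self.mean_high, self.sd_high)
        with np.errstate(invalid="ignore"):
            p = lo / (lo + hi)
        return np.where(lo + hi > 0, p, 0.5)


def _em_once(x, mu, sd, w, max_iter, tol):
    n = len(x)
    trace = []
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step
        comp = np.stack(
            [
                w * stats.norm.pdf(x, mu[0], sd[0]),
                (1 - w) * stats.norm.pdf(x, mu[1], sd[1]),
            ]
        )
        total = comp.sum(axis=0)
        total = np.where(total <= 0, np.finfo(float).tiny, total)
        r = comp[0] / total
        ll = float(np.sum(np.log(total)))
        trace.append(ll)
        if ll < ll_prev - 1e-8 * max(abs(ll_prev), 1.0):
            raise AssertionError("EM log-likelihood decreased")
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
        # M step
        n1 = r.sum()
        n2 = n - n1
        if n1 < 1e-10 or n2 < 1e-10:
            break  # component collapsed; keep best so far
        mu = (float((r * x).sum() / n1), float(((1 - r) * x).sum() / n2))
        v1 = float((r * (x - mu[0]) ** 2).sum() / n1)
        v2 = float(((1 - r) * (x - mu[1]) ** 2).sum() / n2)
        sd = (max(np.sqrt(v1), 1e-3), max(np.sqrt(v2), 1e-3))
        w = float(n1 / n)
    return mu, sd, w, trace[-1], it, converged, np.array(trace)


def fit_mixture_em(flight_hours, cfg: StopoverConfig | None = None) -> MixtureFit:
    """Fit the two-component normal mixture by EM.

    Deterministic initialisation at the 25th/75th percentiles plus
    ``n_random_starts - 1`` jittered restarts; the best final
    log-likelihood wins.  Components are labelled by mean order.
    """
    cfg = cfg or StopoverConfig()
    x = np.asarray(flight_hours, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 10:
        raise ValueError("need at least 10 finite values")
    if np.std(x) < 1e-12:
        raise ValueError("zero-variance input: mixture is degenerate")

    q25, q75 = np.percentile(x, [25, 75])
    sd0 = max(np.std(x) / 2.0, 1e-3)
    rng = np.random.default_rng(cfg.seed)
    starts = [((q25, q75), (sd0, sd0), 0.5)]
    for _ in range(cfg.n_random_starts - 1):
        jit = rng.normal(0, 0.3, 2) * sd0
        starts.append(
            (
                (q25 + jit[0], q75 + jit[1]),
                (sd0 * rng.uniform(0.5, 1.5), sd0 * rng.uniform(0.5, 1.5)),
                float(rng.uniform(0.3, 0.7)),
            )
        )

    best = None
    for mu, sd, w in starts:
        mu, sd, w, ll, it, conv, trace = _em_once(
            x, list(mu), list(sd), w, cfg.max_iter, cfg.tol
        )
        if best is None or ll > best[3]:
            best = (mu, sd, w, ll, it, conv, trace)
    mu, sd, w, ll, it, conv, trace = best
    if mu[0] > mu[1]:  # label by mean order
        mu, sd, w = (mu[1], mu[0]), (sd[1], sd[0]), 1 - w
    return MixtureFit(
        mean_low=mu[0], mean_high=mu[1], sd_low=sd[0], sd_high=sd[1],
        weight_low=w, log_likelihood=ll, iterations=it, converged=conv,
        loglik_trace=trace,
    )


def assign_stopover_days(fit: MixtureFit, flight_hours,
                         cfg: StopoverConfig | None = None) -> np.ndarray:
    """Boolean stopover flags: posterior of the low component strictly
    greater than the threshold."""
    cfg = cfg or StopoverConfig()
    post = fit.posterior_low(np.asarray(flight_hours, dtype=float))
    return post > cfg.posterior_threshold


@dataclass
class Stopover:
    start: dt.date
    end: dt.date  # inclusive
    length_days: int
    lon: float
    lat: float

    @property
    def dates(self):
        return [
            self.start + dt.timedelta(days=i) for i in range(self.length_days)
        ]


@dataclass
class StopoverSet:
    bird_id: str
    stopovers: list[Stopover]

    @property
    def n_stopovers(self) -> int:
        return len(self.stopovers)

    @property
    def total_stopover_days(self) -> int:
        return sum(s.length_days for s in self.stopovers)

    @property
    def gaps_days(self) -> list[int]:
        out = []
        for a, b in zip(self.stopovers, self.stopovers[1:]):
            out.append((b.start - a.end).days - 1)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "bird_id": self.bird_id,
                    "start": s.start,
                    "end": s.end,
                    "length_days": s.length_days,
                    "lon": s.lon,
                    "lat": s.lat,
                }
                for s in self.stopovers
            ]
        )


def segment_stopovers(dates, flags, track=None, bird_id="") -> StopoverSet:
    """Merge consecutive flagged days into stopover segments.

    ``dates`` must be consecutive calendar days within the migration
    window; ``track`` (a geolocate.PositionTrack) supplies the smoothed
    longitude and equinox-masked latitude for centroids.
    """
    dates = list(dates)
    flags = np.asarray(flags, dtype=bool)
    stops = []
    i = 0
    while i < len(dates):
        if flags[i]:
            j = i
            while j + 1 < len(dates) and flags[j + 1] and (
                dates[j + 1] - dates[j]
            ).days == 1:
                j += 1
            seg_dates = dates[i : j + 1]
            lon, lat = _centroid(seg_dates, track)
            stops.append(
                Stopover(
                    start=seg_dates[0], end=seg_dates[-1],
                    length_days=len(seg_dates), lon=lon, lat=lat,
                )
            )
            i = j + 1
        else:
            i += 1
    return StopoverSet(bird_id=bird_id, stopovers=stops)


def _centroid(seg_dates, track):
    if track is None:
        return np.nan, np.nan
    lons = [
        track.smoothed_lon.get(d, np.nan) for d in seg_dates
    ]
    pos = track.positions
    lat_vals = pos[
        pos["date"].isin(seg_dates) & ~pos["equinox_flag"]
    ]["lat"].to_numpy(dtype=float)
    lat = float(np.nanmean(lat_vals)) if np.isfinite(lat_vals).any() else np.nan
    lon = float(np.nanmean(np.asarray(lons, dtype=float)))
    return lon, lat


def daily_flight_totals(birdday: pd.DataFrame) -> pd.DataFrame:
    """Whole-day (day + night) flight hours per (bird_id, date); days with
    a missing phase are dropped rather than imputed."""
    counts = birdday.groupby(["bird_id", "date"])["phase"].nunique()
    tot = birdday.groupby(["bird_id", "date"], as_index=False).agg(
        flight_hours_total=("flight_hours", "sum"),
        forage_hours_total=("forage_hours", "sum"),
    )
    tot = tot[counts.to_numpy() == 2].reset_index(drop=True)
    return tot
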