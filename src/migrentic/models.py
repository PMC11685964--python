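"""Linear mixed-effects model suite for migration phenology and behaviour.

Ten Gaussian mixed models fitted by maximum likelihood with random
intercepts for bird and year (crossed), likelihood-ratio tests of each
term of interest against the reduced model with that term dropped,
parametric bootstrap 95% confidence intervals (draws from the estimated
sampling distribution of the fixed effects, 1000 by default), and
intra-class correlations for the random effects.

Covariate conventions: migratory departure date enters as days since
1 August centred at the sample mean (so a moon main effect is the effect
at the average departure date); lay date as days since 1 April; moon as
illuminated fraction 0-1.  Colony is a fixed factor with Copeland as the
reference level wherever more than one colony is present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ModelSpec",
    "ModelFit",
    "MODEL_SPECS",
    "fit_lmm",
    "lrt",
    "bootstrap_ci",
    "icc",
    "run_model_suite",
]


@dataclass(frozen=True)
class ModelSpec:
    id: int
    response: str
    terms: tuple[str, ...]  # fixed-effect terms, interactions as "a:b"
    data_key: str  # which prepared table the model uses
    lrt_terms: tuple[str, ...] = ()  # terms tested by LRT
    colony_factor: bool = True
    description: str = ""

    def formula(self, with_colony: bool, colony_ref: str | None,
                drop: str | None = None) -> str:
        terms = [t for t in self.terms if t != drop]
        if self.colony_factor and with_colony:
            if drop != "colony":
                ref = (
                    f", Treatment('{colony_ref}')" if colony_ref else ""
                )
                terms.append(f"C(colony{ref})")
        rhs = " + ".join(terms) if terms else "1"
        return f"{self.response} ~ {rhs}"


MODEL_SPECS: tuple[ModelSpec, ...] = (
    ModelSpec(1, "flight_hours",
              ("is_night", "dep_c", "is_night:dep_c"), "daynight",
              lrt_terms=("is_night", "dep_c", "is_night:dep_c", "colony"),
              description="hours of flight per day/night while migrating"),
    ModelSpec(2, "flight_hours",
              ("moon", "dep_c", "moon:dep_c"), "night",
              lrt_terms=("moon", "dep_c", "moon:dep_c", "colony"),
              description="hours of night flight vs moon illumination"),
    ModelSpec(3, "flight_proportion", ("moon_up",), "night",
              lrt_terms=("moon_up", "colony"),
              description="proportion of night spent flying vs moon-up"),
    ModelSpec(4, "forage_hours",
              ("moon", "dep_c", "moon:dep_c"), "night",
              lrt_terms=("moon", "dep_c", "moon:dep_c", "colony"),
              description="hours of night foraging vs moon illumination"),
    ModelSpec(5, "total_stopover_days", ("dep_c",), "birds",
              lrt_terms=("dep_c", "colony"),
              description="total stopover days vs departure date"),
    ModelSpec(6, "stopover_forage_hours", ("dep_c",), "birds",
              lrt_terms=("dep_c", "colony"),
              description="daily foraging hours at stopovers vs departure"),
    ModelSpec(7, "duration_days",
              ("mean_moon_c", "dep_c", "mean_moon_c:dep_c"), "birds",
              lrt_terms=("mean_moon_c", "dep_c", "mean_moon_c:dep_c", "colony"),
              description="migration duration vs mean moon and departure"),
    ModelSpec(8, "departure", ("lay",), "birds_lay",
              lrt_terms=("lay",), colony_factor=False,
              description="departure date vs lay date"),
    ModelSpec(9, "breeding_period", ("lay",), "birds_lay",
              lrt_terms=("lay",), colony_factor=False,
              description="breeding period vs lay date"),
    ModelSpec(10, "mean_chl_ratio", ("dep_c",), "birds",
              lrt_terms=("dep_c", "colony"),
              description="stopover/over-wintering chlorophyll ratio"),
)


@dataclass
class ModelFit:
    model_id: int
    formula: str
    params: pd.Series
    cov_params: pd.DataFrame
    loglik: float
    n_obs: int
    n_fixed: int
    vcomp: dict  # grouping -> variance
    resid_var: float
    converged: bool
    singular: bool
    groups_used: tuple[str, ...]
    data: pd.DataFrame = field(repr=False, default=None)
    spec: ModelSpec = field(repr=False, default=None)
    with_colony: bool = False
    colony_ref: str | None = None
    warnings: list = field(default_factory=list)

    def ci(self, n_boot=1000, seed=0) -> pd.DataFrame:
        return bootstrap_ci(self, n_boot=n_boot, seed=seed)


def _available_groups(data: pd.DataFrame, groups) -> tuple[list, list]:
    used, dropped = [], []
    for g in groups:
        if g in data.columns and data[g].nunique() >= 2:
            used.append(g)
        else:
            dropped.append(g)
    return used, dropped


def fit_lmm(formula: str, data: pd.DataFrame,
            groups=("bird", "year"), model_id: int = 0,
            spec: ModelSpec | None = None, with_colony: bool = False,
            colony_ref: str | None = None) -> ModelFit:
    """ML fit of a Gaussian mixed model with crossed random intercepts.

    Random groupings with fewer than two levels are dropped with a logged
    warning; with no groupings left the fit degenerates to OLS (its exact
    zero-random-variance limit).  Singular (boundary) variance estimates
    are retained, flagged, not refitted.
    """
    data = data.copy()
    used, dropped = _available_groups(data, groups)
    warns = [f"random intercept '{g}' dropped (<2 levels)" for g in dropped]

    if used:
        data["_one"] = 1
        vcf = {g: f"0 + C({g})" for g in used}
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            model = sm.MixedLM.from_formula(
                formula, groups="_one", vc_formula=vcf, re_formula="0",
                data=data,
            )
            res = model.fit(reml=False)
        fe = res.fe_params
        k = len(fe)
        cov = pd.DataFrame(
            np.asarray(res.cov_params())[:k, :k], index=fe.index,
            columns=fe.index,
        )
        vcomp = dict(zip(model.exog_vc.names, np.maximum(res.vcomp, 0.0)))
        singular = bool(np.any(res.vcomp <= 1e-10))
        converged = bool(getattr(res, "converged", True))
        warns += [str(w.message) for w in wlist
                  if "converge" in str(w.message).lower()]
        return ModelFit(
            model_id=model_id, formula=formula, params=fe, cov_params=cov,
            loglik=float(res.llf), n_obs=int(res.nobs), n_fixed=k,
            vcomp=vcomp, resid_var=float(res.scale), converged=converged,
            singular=singular, groups_used=tuple(used), data=data,
            spec=spec, with_colony=with_colony, colony_ref=colony_ref,
            warnings=warns,
        )

    res = sm.OLS.from_formula(formula, data=data).fit()
    # ML residual variance (OLS llf already uses the ML sigma-hat)
    return ModelFit(
        model_id=model_id, formula=formula, params=res.params,
        cov_params=pd.DataFrame(
            res.cov_params(), index=res.params.index, columns=res.params.index
        ),
        loglik=float(res.llf), n_obs=int(res.nobs),
        n_fixed=len(res.params),
        vcomp={}, resid_var=float(res.ssr / res.nobs), converged=True,
        singular=False, groups_used=(), data=data, spec=spec,
        with_colony=with_colony, colony_ref=colony_ref, warnings=warns,
    )


def lrt(full: ModelFit, reduced: ModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio test: chi2 = 2 (ll_full - ll_reduced), df = fixed
    parameter difference, p from the chi-squared distribution."""
    df = full.n_fixed - reduced.n_fixed
    if df < 0 or full.n_obs != reduced.n_obs:
        raise ValueError("reduced model must be nested in the full model")
    if df == 0 and full.formula == reduced.formula:
        return 0.0, 0, 1.0
    chi2 = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return float(chi2), int(df), p


def lrt_term(fit: ModelFit, term: str) -> tuple[float, int, float]:
    """LRT of one term (or the whole colony factor) of a suite model."""
    if fit.spec is None:
        raise ValueError("fit carries no ModelSpec; use lrt(full, reduced)")
    formula = fit.spec.formula(fit.with_colony, fit.colony_ref, drop=term)
    reduced = fit_lmm(
        formula, fit.data, groups=fit.groups_used or ("bird", "year"),
        model_id=fit.model_id, spec=fit.spec,
        with_colony=fit.with_colony and term != "colony",
        colony_ref=fit.colony_ref,
    )
    return lrt(fit, reduced)


def bootstrap_ci(fit: ModelFit, n_boot: int = 1000, seed: int = 0,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Parametric bootstrap CIs: draw coefficient vectors from the
    estimated sampling distribution N(beta-hat, Cov-hat) and take
    percentiles.  Reproducible given the seed."""
    rng = np.random.default_rng(seed)
    cov = fit.cov_params.to_numpy()
    # symmetrise; a deterministic (zero-residual) fit can leave NaN/inf in
    # the covariance, which collapses to a zero-width interval
    cov = np.nan_to_num((cov + cov.T) / 2.0, nan=0.0, posinf=0.0, neginf=0.0)
    # clip tiny negative eigenvalues so the draw is from a valid PSD matrix
    w, v = np.linalg.eigh(cov)
    cov = (v * np.clip(w, 0.0, None)) @ v.T
    draws = rng.multivariate_normal(
        fit.params.to_numpy(), cov, size=n_boot, method="svd"
    )
    lo, hi = np.percentile(
        draws, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0
    )
    return pd.DataFrame(
        {"estimate": fit.params, "ci_lo": lo, "ci_hi": hi},
        index=fit.params.index,
    )


def icc(fit: ModelFit, grouping: str) -> float:
    """Share of total random variance attributable to one grouping."""
    if grouping not in fit.vcomp:
        return 0.0
    total = sum(fit.vcomp.values()) + fit.resid_var
    return float(fit.vcomp[grouping] / total) if total > 0 else 0.0


# ---------------------------------------------------------------------------
# the suite


def _prepare(tables: dict) -> dict:
    """Derive the per-spec data keys from the prepared tables dict with
    keys 'birdday' (per bird-day-phase rows inside the migration window,
    stopover-flagged) and 'birds' (per bird-year summaries)."""
    out = {}
    bd = tables.get("birdday")
    if bd is not None and not bd.empty:
        mig = bd[~bd["is_stopover_day"]].copy()
        mig["is_night"] = (mig["phase"] == "night").astype(float)
        mig = mig.rename(columns={"moon_illumination": "moon",
                                  "moon_up_fraction": "moon_up"})
        out["daynight"] = mig
        out["night"] = mig[mig["phase"] == "night"].copy()
    birds = tables.get("birds")
    if birds is not None and not birds.empty:
        birds = birds.copy()
        if "mean_moon" in birds.columns and "mean_moon_c" not in birds.columns:
            # centred so the departure main effect is evaluated at the
            # average moon exposure, not extrapolated to "no moon"
            birds["mean_moon_c"] = birds["mean_moon"] - birds["mean_moon"].mean()
        out["birds"] = birds
        if "lay" in birds.columns:
            lay = birds.dropna(subset=["lay"]).copy()
            if not lay.empty:
                lay["breeding_period"] = lay["departure_abs"] - lay["lay_abs"]
                out["birds_lay"] = lay
    return out


def run_model_suite(tables: dict, n_boot: int = 1000, seed: int = 0,
                    do_lrt: bool = True) -> dict:
    """Fit models 1-10 on the prepared tables.

    Returns {'fits': {id: ModelFit}, 'table': tidy report, 'skipped':
    {id: reason}}.  The tidy table has one row per coefficient with the
    bootstrap CI and, for tested terms, the LRT chi2/df/p; plus one ICC row
    per random grouping.
    """
    prepared = _prepare(tables)
    fits, skipped, rows = {}, {}, []
    rng = np.random.default_rng(seed)
    for spec in MODEL_SPECS:
        data = prepared.get(spec.data_key)
        if data is None or data.empty:
            skipped[spec.id] = f"missing input table '{spec.data_key}'"
            continue
        missing = [
            c for t in spec.terms for c in t.split(":") if c not in data.columns
        ]
        if spec.response not in data.columns or missing:
            skipped[spec.id] = (
                f"missing columns: {[spec.response] + missing}"
            )
            continue
        sub = data.dropna(
            subset=[spec.response] + sorted({c for t in spec.terms
                                             for c in t.split(":")})
        )
        if len(sub) < 10:
            skipped[spec.id] = "fewer than 10 usable rows"
            continue
        with_colony = (
            spec.colony_factor
            and "colony" in sub.columns
            and sub["colony"].nunique() >= 2
        )
        colony_ref = (
            "Copeland"
            if with_colony and (sub["colony"] == "Copeland").any()
            else None
        )
        formula = spec.formula(with_colony, colony_ref)
        fit = fit_lmm(
            formula, sub, model_id=spec.id, spec=spec,
            with_colony=with_colony, colony_ref=colony_ref,
        )
        fits[spec.id] = fit

        ci = bootstrap_ci(fit, n_boot=n_boot,
                          seed=int(rng.integers(0, 2**31 - 1)))
        lrt_results = {}
        if do_lrt:
            for term in spec.lrt_terms:
                if term == "colony" and not with_colony:
                    continue
                try:
                    lrt_results[term] = lrt_term(fit, term)
                except Exception as e:  # pragma: no cover - defensive
                    lrt_results[term] = (np.nan, 0, np.nan)
                    fit.warnings.append(f"LRT failed for {term}: {e}")
        for name in fit.params.index:
            term = _param_to_term(name, spec)
            chi2, dfree, p = lrt_results.get(term, (np.nan, 0, np.nan))
            rows.append(
                {
                    "model_id": spec.id, "term": name,
                    "estimate": fit.params[name],
                    "ci_lo": ci.loc[name, "ci_lo"],
                    "ci_hi": ci.loc[name, "ci_hi"],
                    "chisq": chi2, "df": dfree, "p": p,
                }
            )
        for g in fit.groups_used:
            rows.append(
                {
                    "model_id": spec.id, "term": f"ICC({g})",
                    "estimate": icc(fit, g), "ci_lo": np.nan,
                    "ci_hi": np.nan, "chisq": np.nan, "df": 0, "p": np.nan,
                }
            )
    return {"fits": fits, "table": pd.DataFrame(rows), "skipped": skipped}


def _param_to_term(param_name: str, spec: ModelSpec) -> str:
    if param_name.startswith("C(colony"):
        return "colony"
    for t in spec.terms:
        if set(t.split(":")) == set(param_name.split(":")):
            return t
    return param_name
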