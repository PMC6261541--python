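"""Synthetic study inputs with known ground truth.

Generates every table the pipeline consumes — team game logs, hourly solar
irradiance, county-day sentiment with tweet counts, postal-day lottery
sales, populations, geography and daily weather — from an explicit
generative model that mirrors the assumptions of the downstream analysis:

* team strengths follow a bounded random walk and outcomes are Bernoulli
  (with occasional ties and doubleheaders);
* daily irradiance is a seasonal sinusoid plus an AR(1) weather factor,
  expanded to a diurnal hourly profile with zero night hours; per-MSA
  variability spans a calm (Los Angeles-like) to volatile (Dallas-like)
  range;
* county-day mood is linear in the lagged z-scored citywide sports PE and
  the same-day z-scored sunshine PE, plus day-of-week/month effects, nested
  MSA/county random intercepts, and Gaussian noise;
* postal-day log per-capita lottery purchases are linear in the same PEs
  (direct path), standardized county mood (mediated path), paycheck and
  calendar effects, nested random intercepts, and noise.

Each table draws from its own named substream of the master seed, so
regenerating one table never perturbs the others.  The realized intercepts,
effect sizes and latent PE series are returned as ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import calendar_design
from .prediction_error import CityPESeries, build_pe_series

__all__ = ["SimConfig", "gen_sports", "gen_irradiance", "gen_weather",
           "gen_mood_panel", "gen_lottery_panel", "simulate"]

_STREAMS = {"sports": 0, "irradiance": 1, "mood": 2, "lottery": 3,
            "weather": 4, "population": 5}

#: per-team season lengths cycled across a city's franchises (basketball /
#: baseball / hockey / football-like)
_SEASON_GAMES = (82, 162, 82, 16)


@dataclass
class SimConfig:
    """Knobs of the generative model; defaults are the study conditions."""

    n_msas: int = 6
    counties_per_msa: int = 4
    postal_per_msa: int = 20
    gambling_msas: int = 2
    teams_per_msa: int = 3
    n_days: int = 365
    start_date: str = "2013-01-01"
    alpha: float = 0.1

    # sports
    strength_init: float | None = None      # None: uniform in [0.35, 0.65]
    strength_drift_sd: float = 0.02
    tie_prob: float = 0.02
    doubleheader_frac: float = 0.03         # MLB-like teams only

    # irradiance (W/m^2)
    irradiance_base: float = 450.0
    irradiance_seasonal_amp: float = 150.0
    irradiance_var_low: float = 60.0
    irradiance_var_high: float = 130.0
    irradiance_ar1: float = 0.4

    # mood (valence model units)
    mood_mu: float = 0.0
    beta_pe_mood: float = 0.002             # lag-1 sports PE, per SD
    beta_sun_mood: float = 0.002            # same-day sunshine PE, per SD
    mood_calendar_sd: float = 0.005
    mood_msa_sd: float = 0.01
    mood_county_sd: float = 0.005
    mood_resid_sd: float = 0.02

    # tweet-count coverage process
    tweet_base_low: int = 200
    tweet_base_high: int = 2000
    coverage_dropout: float = 0.05
    include_low_coverage: bool = True
    low_coverage_dropout: float = 0.5

    # gambling (log USD/adult/day)
    gambling_nu: float = -1.2
    beta_mood_gambling: float = 0.005       # per SD of mood
    beta_pe_gambling_direct: float = 0.003  # per SD of PE (both sources)
    paycheck_effect: float = 0.01
    gambling_calendar_sd: float = 0.003
    gambling_msa_sd: float = 0.01
    gambling_postal_sd: float = 0.01
    gambling_resid_sd: float = 0.02
    low_pop_frac: float = 0.15              # postal codes drawn under the floor

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 30:
            raise ValueError("n_days must be >= 30")
        for name in ("strength_drift_sd", "mood_resid_sd", "gambling_resid_sd",
                     "mood_msa_sd", "mood_county_sd", "gambling_msa_sd",
                     "gambling_postal_sd", "mood_calendar_sd", "gambling_calendar_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("tie_prob", "coverage_dropout", "low_coverage_dropout",
                     "doubleheader_frac", "low_pop_frac"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")

    # -- derived identifiers -------------------------------------------
    @property
    def calendar(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=self.n_days, freq="D")

    @property
    def msa_ids(self) -> list[str]:
        return [f"msa{i + 1:02d}" for i in range(self.n_msas)]

    def counties(self, msa: str) -> list[str]:
        base = [f"{msa}_cty{j + 1}" for j in range(self.counties_per_msa)]
        if self.include_low_coverage:
            base.append(f"{msa}_ctyX")
        return base

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_STREAMS[stream],))
        )


def gen_sports(config: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Season game logs per team with latent strength random walks."""
    rng = config.rng("sports")
    cal = config.calendar
    rows = []
    strengths: dict[str, list[float]] = {}
    for msa in config.msa_ids:
        for k in range(config.teams_per_msa):
            team = f"{msa}_team{k + 1}"
            n_games = min(_SEASON_GAMES[k % len(_SEASON_GAMES)], config.n_days)
            day_idx = np.sort(rng.choice(config.n_days, size=n_games, replace=False))
            if n_games > 120 and config.doubleheader_frac > 0:
                n_dh = rng.binomial(n_games, config.doubleheader_frac)
                extra = rng.choice(day_idx, size=n_dh, replace=False)
                day_idx = np.sort(np.concatenate([day_idx, extra]))
            if config.strength_init is None:
                s = rng.uniform(0.35, 0.65)
            else:
                s = config.strength_init
            path = []
            for d in day_idx:
                s = float(np.clip(s + rng.normal(0, config.strength_drift_sd), 0.05, 0.95)) \
                    if config.strength_drift_sd > 0 else s
                path.append(s)
                if config.tie_prob > 0 and rng.random() < config.tie_prob:
                    outcome = 0.5
                else:
                    outcome = float(rng.random() < s)
                rows.append((cal[d], msa, team, outcome))
            strengths[team] = path
    games = pd.DataFrame(rows, columns=["date", "msa_id", "team_id", "outcome"])
    games = games.sort_values(["msa_id", "team_id", "date"], kind="stable").reset_index(drop=True)
    return games, {"strengths": strengths}


def _daylight_profile(doy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hour-of-day weights (24 per day) with a season-varying daylight window."""
    half_width = 4.5 + 1.5 * np.cos(2 * np.pi * (doy - 172) / 365.25)
    hours = np.arange(24)
    rel = (hours[None, :] - 12.0) / half_width[:, None]
    shape = np.where(np.abs(rel) < 1.0, np.cos(0.5 * np.pi * rel), 0.0)
    shape = np.clip(shape, 0.0, None)
    mean_pos = np.array([row[row > 0].mean() for row in shape])
    return shape, mean_pos


def gen_irradiance(config: SimConfig) -> pd.DataFrame:
    """Hourly DNI per MSA: seasonal mean + AR(1) weather, zero at night."""
    rng = config.rng("irradiance")
    cal = config.calendar
    doy = cal.dayofyear.to_numpy()
    shape, mean_pos = _daylight_profile(doy)
    if config.n_msas > 1:
        variabilities = np.linspace(
            config.irradiance_var_low, config.irradiance_var_high, config.n_msas
        )
    else:
        variabilities = np.array([config.irradiance_var_low])
    frames = []
    for msa, v in zip(config.msa_ids, variabilities):
        x = 0.0
        daily = np.empty(config.n_days)
        rho = config.irradiance_ar1
        for d in range(config.n_days):
            x = rho * x + math.sqrt(1 - rho**2) * rng.normal()
            seasonal = config.irradiance_seasonal_amp * np.cos(
                2 * np.pi * (doy[d] - 172) / 365.25
            )
            daily[d] = max(config.irradiance_base + seasonal + v * x, 0.0)
        hourly = daily[:, None] * shape / mean_pos[:, None]
        ts = np.repeat(cal.values, 24) + np.tile(
            pd.to_timedelta(np.arange(24), unit="h"), config.n_days
        )
        frames.append(pd.DataFrame({
            "timestamp": ts,
            "msa_id": msa,
            "dni_wm2": hourly.ravel(),
        }))
    return pd.concat(frames, ignore_index=True)


def gen_weather(config: SimConfig) -> pd.DataFrame:
    """Daily snow/visibility rows; blizzards arise in winter months."""
    rng = config.rng("weather")
    cal = config.calendar
    frames = []
    for msa in config.msa_ids:
        winter = np.isin(cal.month, (1, 2, 3, 11, 12))
        snow = (rng.random(config.n_days) < 0.08) & winter
        vis = np.where(
            snow, rng.uniform(2.0, 10.0, config.n_days), rng.uniform(6.0, 10.0, config.n_days)
        )
        frames.append(pd.DataFrame({
            "date": cal, "msa_id": msa,
            "snow": snow.astype(int), "visibility_miles": np.round(vis, 1),
        }))
    return pd.concat(frames, ignore_index=True)


def _pooled_z(per_msa: dict[str, np.ndarray]) -> tuple[dict[str, np.ndarray], float, float]:
    pooled = np.concatenate([v[np.isfinite(v)] for v in per_msa.values()])
    mu, sd = float(np.mean(pooled)), float(np.std(pooled, ddof=1))
    if sd == 0:
        return {k: np.zeros_like(v) for k, v in per_msa.items()}, mu, 1.0
    return {k: (v - mu) / sd for k, v in per_msa.items()}, mu, sd


def gen_mood_panel(
    config: SimConfig,
    pe_sports: dict[str, CityPESeries],
    pe_sunshine: dict[str, CityPESeries],
) -> tuple[pd.DataFrame, dict]:
    """County-day sentiment rows generated from the linear mood model.

    PEs enter as z-scores standardized over the pooled MSA-day values on the
    days the downstream panel will model (all days with a defined lagged
    sports PE), so the generating coefficients are on the same per-SD scale
    the fitted model reports.
    """
    rng = config.rng("mood")
    cal = config.calendar
    n = config.n_days

    # lag-1 sports PE and lag-0 sunshine PE aligned to the mood day
    sports_lag = {
        m: np.concatenate([[np.nan], s.pe_sum.to_numpy()[:-1]]) for m, s in pe_sports.items()
    }
    sun_same = {m: s.pe_sum.to_numpy() for m, s in pe_sunshine.items()}
    model_days = ~np.isnan(next(iter(sports_lag.values())))
    z_sports, mu_s, sd_s = _pooled_z({m: v[model_days] for m, v in sports_lag.items()})
    z_sun, mu_w, sd_w = _pooled_z({m: v[model_days] for m, v in sun_same.items()})

    dow_eff = rng.normal(0, config.mood_calendar_sd, 7)
    month_eff = rng.normal(0, config.mood_calendar_sd, 12)
    dow = cal.weekday.to_numpy()
    month = cal.month.to_numpy() - 1

    rows = []
    truth: dict = {
        "beta_pe_mood": config.beta_pe_mood,
        "beta_sun_mood": config.beta_sun_mood,
        "mood_dow_effects": dow_eff.tolist(),
        "mood_month_effects": month_eff.tolist(),
        "pe_sports_scale": {"mean": mu_s, "sd": sd_s},
        "pe_sunshine_scale": {"mean": mu_w, "sd": sd_w},
        "mood_intercepts": {},
        "valid_counties": {},
    }
    for msa in config.msa_ids:
        u_msa = rng.normal(0, config.mood_msa_sd)
        zs = np.zeros(n)
        zs[model_days] = z_sports[msa]
        zw = np.zeros(n)
        zw[model_days] = z_sun[msa]
        truth["valid_counties"][msa] = []
        for county in config.counties(msa):
            low = county.endswith("X")
            u_cty = rng.normal(0, config.mood_county_sd)
            truth["mood_intercepts"][county] = {"msa": u_msa, "county": u_cty}
            if not low:
                truth["valid_counties"][msa].append(county)
            mood = (
                config.mood_mu
                + config.beta_pe_mood * zs
                + config.beta_sun_mood * zw
                + dow_eff[dow]
                + month_eff[month]
                + u_msa
                + u_cty
                + rng.normal(0, config.mood_resid_sd, n)
            )
            base = rng.integers(config.tweet_base_low, config.tweet_base_high + 1)
            dropout = config.low_coverage_dropout if low else config.coverage_dropout
            sparse_day = rng.random(n) < dropout
            counts = np.where(
                sparse_day, rng.poisson(30, n), rng.poisson(base, n)
            )
            rows.append(pd.DataFrame({
                "date": cal, "msa_id": msa, "county_id": county,
                "mean_valence": np.round(mood, 6), "n_tweets": counts,
            }))
    sentiment = pd.concat(rows, ignore_index=True)
    return sentiment, truth


def gen_lottery_panel(
    config: SimConfig,
    sentiment: pd.DataFrame,
    pe_sports: dict[str, CityPESeries],
    pe_sunshine: dict[str, CityPESeries],
    mood_truth: dict,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Postal-day lottery sales implementing the mediation structure.

    The mediated path uses county mood standardized over the realized
    gambling-MSA mood values, so the generating coefficient is per SD of
    mood as fitted downstream; the direct path reuses the PE z-scales fitted
    in the mood generator.
    """
    rng = config.rng("lottery")
    prng = config.rng("population")
    cal = config.calendar
    n = config.n_days
    g_msas = config.msa_ids[: config.gambling_msas]

    mood_wide = sentiment.pivot(index="date", columns="county_id", values="mean_valence")
    # standardize over the county-days the gambling panel will model:
    # coverage-retained counties, days with a defined lagged sports PE
    g_counties = [c for m in g_msas for c in mood_truth["valid_counties"][m]]
    pooled_mood = mood_wide[g_counties].iloc[1:].to_numpy().ravel()
    mood_mu = float(np.nanmean(pooled_mood))
    mood_sd = float(np.nanstd(pooled_mood, ddof=1))

    sd_s = mood_truth["pe_sports_scale"]
    sd_w = mood_truth["pe_sunshine_scale"]

    dow_eff = rng.normal(0, config.gambling_calendar_sd, 7)
    month_eff = rng.normal(0, config.gambling_calendar_sd, 12)
    dow = cal.weekday.to_numpy()
    month = cal.month.to_numpy() - 1
    paycheck = calendar_design.paycheck_days(cal).to_numpy()

    lottery_rows, geo_rows, pop_rows = [], [], []
    truth = {
        "beta_mood_gambling": config.beta_mood_gambling,
        "beta_pe_gambling_direct": config.beta_pe_gambling_direct,
        "paycheck_effect": config.paycheck_effect,
        "gambling_mood_scale": {"mean": mood_mu, "sd": mood_sd},
        "gambling_intercepts": {},
        "gambling_msas": g_msas,
    }
    for msa in g_msas:
        u_msa = rng.normal(0, config.gambling_msa_sd)
        counties = config.counties(msa)
        zs = np.concatenate([[0.0], pe_sports[msa].pe_sum.to_numpy()[:-1]])
        zs = (zs - sd_s["mean"]) / sd_s["sd"]
        zs[0] = 0.0
        zw = (pe_sunshine[msa].pe_sum.to_numpy() - sd_w["mean"]) / sd_w["sd"]
        for j in range(config.postal_per_msa):
            postal = f"{msa}_p{j + 1:03d}"
            county = counties[j % len(counties)]
            if prng.random() < config.low_pop_frac:
                adult_pop = int(prng.uniform(5_000, 14_999))
            else:
                adult_pop = int(prng.lognormal(math.log(30_000), 0.4))
            u_postal = rng.normal(0, config.gambling_postal_sd)
            truth["gambling_intercepts"][postal] = {"msa": u_msa, "postal": u_postal}
            mood_z = (mood_wide[county].to_numpy() - mood_mu) / mood_sd
            log_pc = (
                config.gambling_nu
                + config.beta_pe_gambling_direct * zs
                + config.beta_pe_gambling_direct * zw
                + config.beta_mood_gambling * mood_z
                + config.paycheck_effect * paycheck
                + dow_eff[dow]
                + month_eff[month]
                + u_msa
                + u_postal
                + rng.normal(0, config.gambling_resid_sd, n)
            )
            sales = adult_pop * np.exp(log_pc)
            lottery_rows.append(pd.DataFrame({
                "date": cal, "postal_code": postal, "sales_usd": np.round(sales, 2),
            }))
            geo_rows.append((postal, county, msa))
            pop_rows.append((postal, adult_pop, adult_pop))

    lottery = pd.concat(lottery_rows, ignore_index=True)
    geography = pd.DataFrame(geo_rows, columns=["postal_code", "county_id", "msa_id"])
    # county rows for the mood-model population weights
    for msa in config.msa_ids:
        for county in config.counties(msa):
            total = int(prng.lognormal(math.log(1_000_000), 0.5))
            pop_rows.append((county, int(total * 0.75), total))
    population = pd.DataFrame(
        pop_rows, columns=["unit_id", "adult_population", "total_population"]
    )
    return lottery, population, geography, truth


def simulate(config: SimConfig) -> tuple[dict[str, pd.DataFrame], dict]:
    """Generate every input table plus the ground-truth record."""
    games, sports_truth = gen_sports(config)
    irradiance = gen_irradiance(config)
    weather = gen_weather(config)
    pe_sports, pe_sun = build_pe_series(games, irradiance, config.calendar, config.alpha)
    sentiment, mood_truth = gen_mood_panel(config, pe_sports, pe_sun)
    lottery, population, geography, gamb_truth = gen_lottery_panel(
        config, sentiment, pe_sports, pe_sun, mood_truth
    )
    tables = {
        "games": games,
        "irradiance": irradiance,
        "weather": weather,
        "sentiment": sentiment,
        "lottery": lottery,
        "population": population,
        "geography": geography,
    }
    truth = {
        "config": asdict(config),
        "sports": sports_truth,
        "mood": mood_truth,
        "gambling": gamb_truth,
        "pe_sports": {m: s.pe_sum.tolist() for m, s in pe_sports.items()},
        "pe_sunshine": {m: s.pe_sum.tolist() for m, s in pe_sun.items()},
    }
    return tables, truth
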