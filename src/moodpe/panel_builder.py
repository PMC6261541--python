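"""Assembly of analysis-ready county-day and postal-day panels.

Raw inputs (county-day sentiment, postal-day lottery sales, citywide PE
series, populations, calendar design) are filtered, transformed and joined
into long-format modelling panels:

* counties must have >= 100 tweets on >= 80% of calendar days;
* postal codes must have >= 15,000 adult residents;
* lottery sales become log per-capita purchase rates (USD/adult/day);
* predictors of interest are z-scored over the pooled modelling dataset;
* the mood row at date d carries the sports PE from d-1 and the sunshine PE
  from d (lags configurable).

Population weights (total population for counties, adult population for
postal codes) ride along for use as regression sample weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prediction_error import CityPESeries

__all__ = [
    "ZScaler",
    "coverage_filter",
    "population_filter",
    "per_capita_log",
    "zscore",
    "align_lags",
    "build_mood_panel",
    "build_gambling_panel",
]

DEFAULT_MIN_TWEETS = 100
DEFAULT_MIN_FRAC = 0.80
DEFAULT_MIN_POP = 15_000
DEFAULT_LOG_EPS = 1e-6


@dataclass
class ZScaler:
    """Affine standardizer whose parameters can be reused across panels."""

    mean: float
    sd: float

    @classmethod
    def fit(cls, series) -> "ZScaler":
        x = np.asarray(series, dtype=float)
        x = x[np.isfinite(x)]
        sd = float(np.std(x, ddof=1))
        if not np.isfinite(sd) or sd == 0.0:
            raise ValueError("cannot z-score a constant series")
        return cls(mean=float(np.mean(x)), sd=sd)

    def transform(self, series):
        return (series - self.mean) / self.sd


def zscore(series) -> pd.Series:
    """Standardize to mean 0, sample sd 1; constant series are rejected."""
    scaler = ZScaler.fit(series)
    out = scaler.transform(pd.Series(series, dtype=float))
    return out


def coverage_filter(
    tweet_counts: pd.DataFrame,
    calendar,
    min_tweets: int = DEFAULT_MIN_TWEETS,
    min_frac: float = DEFAULT_MIN_FRAC,
) -> list[str]:
    """Counties with enough well-sampled days to trust their mood series.

    A county is retained when the fraction of calendar days having at least
    ``min_tweets`` recorded tweets is at least ``min_frac``; missing
    county-days count as zero tweets.  Thresholds are inclusive.
    """
    calendar = pd.DatetimeIndex(calendar)
    df = tweet_counts.copy()
    df["date"] = pd.to_datetime(df["date"])
    df = df[df["date"].isin(calendar)]
    if df.duplicated(["county_id", "date"]).any():
        raise ValueError("duplicate county-day tweet-count rows")
    ok_days = (
        df.assign(ok=(df["n_tweets"] >= min_tweets).astype(int))
        .groupby("county_id")["ok"]
        .sum()
    )
    frac = ok_days / float(len(calendar))
    retained = sorted(frac[frac >= min_frac].index.astype(str))
    return retained


def population_filter(
    populations: pd.Series | pd.DataFrame,
    min_pop: int = DEFAULT_MIN_POP,
    pop_col: str = "adult_population",
) -> list[str]:
    """Postal codes with at least ``min_pop`` adult residents (inclusive)."""
    if isinstance(populations, pd.DataFrame):
        pop = populations.set_index("unit_id")[pop_col]
    else:
        pop = populations
    if (pop < 0).any():
        raise ValueError("populations must be nonnegative")
    return sorted(pop[pop >= min_pop].index.astype(str))


def per_capita_log(sales_usd, adult_pop, eps: float = DEFAULT_LOG_EPS):
    """Natural log of per-capita daily purchases, log(sales/pop + eps).

    eps keeps rare zero-sales days finite; it is small relative to any
    plausible per-person spend (default 1e-6 USD/person).
    """
    pop = np.asarray(adult_pop, dtype=float)
    if np.any(pop <= 0):
        raise ValueError("adult population must be positive")
    sales = np.asarray(sales_usd, dtype=float)
    if np.any(sales < 0):
        raise ValueError("sales must be nonnegative")
    return np.log(sales / pop + eps)


def align_lags(
    panel: pd.DataFrame,
    pe_sports: dict[str, CityPESeries] | None,
    pe_sunshine: dict[str, CityPESeries] | None,
    sports_lag: int = 1,
    sunshine_lag: int = 0,
) -> pd.DataFrame:
    """Attach lagged citywide PE columns to a long panel keyed by msa_id/date.

    The row at date d receives the sports PE from d - sports_lag and the
    sunshine PE from d - sunshine_lag.  Dates falling before a PE series
    starts produce missing values (dropped by the model), never zeros.
    """
    out = panel.copy()
    for name, series_map, lag in (
        ("pe_sports", pe_sports, sports_lag),
        ("pe_sunshine", pe_sunshine, sunshine_lag),
    ):
        if series_map is None:
            continue
        col = np.full(len(out), np.nan)
        for msa, city in series_map.items():
            s = city.pe_sum if isinstance(city, CityPESeries) else city
            shifted = s.copy()
            shifted.index = shifted.index + pd.Timedelta(days=lag)
            mask = out["msa_id"].astype(str) == str(msa)
            col[mask.values] = shifted.reindex(pd.DatetimeIndex(out.loc[mask, "date"])).values
        out[name] = col
    return out


def _merge_nuisance(panel: pd.DataFrame, nuisance: pd.DataFrame) -> pd.DataFrame:
    """Join nuisance regressors by date, or by (msa_id, date) when the
    design is region-specific (e.g. blizzard flags differ by MSA)."""
    if "msa_id" in nuisance.columns:
        nuis = nuisance.copy()
        nuis["msa_id"] = nuis["msa_id"].astype(str)
        return panel.merge(nuis, on=["msa_id", "date"], how="left", validate="many_to_one")
    return panel.merge(
        nuisance, left_on="date", right_index=True, how="left", validate="many_to_one"
    )


def _check_unique(panel: pd.DataFrame, unit: str) -> None:
    if panel.duplicated([unit, "date"]).any():
        raise ValueError(f"duplicated ({unit}, date) keys after join")


def build_mood_panel(
    sentiment: pd.DataFrame,
    pe_sports: dict[str, CityPESeries],
    pe_sunshine: dict[str, CityPESeries],
    populations: pd.DataFrame,
    nuisance: pd.DataFrame,
    calendar,
    min_tweets: int = DEFAULT_MIN_TWEETS,
    min_frac: float = DEFAULT_MIN_FRAC,
    sports_lag: int = 1,
    sunshine_lag: int = 0,
) -> tuple[pd.DataFrame, dict[str, ZScaler]]:
    """County-day mood panel with z-scored PE columns and county weights.

    Returns the panel and the fitted PE z-scalers so the gambling panel can
    standardize the same PE series on an identical scale.  Counties failing
    the coverage filter are dropped entirely; retained counties keep only
    days with an observed mood value and a defined lagged PE.
    """
    calendar = pd.DatetimeIndex(calendar)
    sent = sentiment.copy()
    sent["date"] = pd.to_datetime(sent["date"])
    keep = coverage_filter(
        sent[["county_id", "date", "n_tweets"]], calendar, min_tweets, min_frac
    )
    panel = sent[sent["county_id"].astype(str).isin(keep)].copy()
    panel = panel.rename(columns={"mean_valence": "mood"})
    _check_unique(panel, "county_id")

    panel = align_lags(panel, pe_sports, pe_sunshine, sports_lag, sunshine_lag)
    panel = panel.dropna(subset=["mood", "pe_sports", "pe_sunshine"])

    scalers = {
        "pe_sports": ZScaler.fit(panel["pe_sports"]),
        "pe_sunshine": ZScaler.fit(panel["pe_sunshine"]),
    }
    panel["pe_sports_z"] = scalers["pe_sports"].transform(panel["pe_sports"])
    panel["pe_sunshine_z"] = scalers["pe_sunshine"].transform(panel["pe_sunshine"])

    pop = populations.set_index(populations["unit_id"].astype(str))["total_population"]
    panel["weight"] = panel["county_id"].astype(str).map(pop)
    if panel["weight"].isna().any():
        missing = sorted(set(panel.loc[panel["weight"].isna(), "county_id"].astype(str)))
        raise ValueError(f"no population for counties: {missing}")
    if (panel["weight"] <= 0).any():
        raise ValueError("county weights must be positive")

    panel = _merge_nuisance(panel, nuisance)
    panel = panel.reset_index(drop=True)
    return panel, scalers


def build_gambling_panel(
    lottery: pd.DataFrame,
    mood_panel: pd.DataFrame,
    geography: pd.DataFrame,
    pe_sports: dict[str, CityPESeries],
    pe_sunshine: dict[str, CityPESeries],
    populations: pd.DataFrame,
    nuisance: pd.DataFrame,
    pe_scalers: dict[str, ZScaler] | None = None,
    min_pop: int = DEFAULT_MIN_POP,
    sports_lag: int = 1,
    sunshine_lag: int = 0,
    log_eps: float = DEFAULT_LOG_EPS,
) -> pd.DataFrame:
    """Postal-day gambling panel joined to county-level same-day mood.

    Postal codes below the adult-population floor, or in counties that failed
    the mood coverage filter, are excluded; mood joins by the postal code's
    county.  PE columns are standardized with the scalers fitted on the mood
    panel when given (keeping treatment units identical across the mediator
    and outcome models), otherwise refit here.
    """
    geo = geography.astype({"postal_code": str, "county_id": str, "msa_id": str})
    pop = populations.set_index(populations["unit_id"].astype(str))["adult_population"]

    lot = lottery.copy()
    lot["date"] = pd.to_datetime(lot["date"])
    lot["postal_code"] = lot["postal_code"].astype(str)
    _check_unique(lot, "postal_code")
    lot = lot.merge(geo, on="postal_code", how="left", validate="many_to_one")
    if lot["county_id"].isna().any():
        missing = sorted(set(lot.loc[lot["county_id"].isna(), "postal_code"]))
        raise ValueError(f"postal codes missing from geography: {missing}")

    keep_pop = set(population_filter(pop, min_pop))
    retained_counties = set(mood_panel["county_id"].astype(str))
    lot = lot[lot["postal_code"].isin(keep_pop)]
    lot = lot[lot["county_id"].isin(retained_counties)].copy()

    lot["weight"] = lot["postal_code"].map(pop)
    lot["log_per_capita"] = per_capita_log(lot["sales_usd"], lot["weight"], eps=log_eps)

    mood = mood_panel[["county_id", "date", "mood"]].copy()
    mood["county_id"] = mood["county_id"].astype(str)
    lot = lot.merge(mood, on=["county_id", "date"], how="inner", validate="many_to_one")

    lot = align_lags(lot, pe_sports, pe_sunshine, sports_lag, sunshine_lag)
    lot = lot.dropna(subset=["pe_sports", "pe_sunshine"])

    for name in ("pe_sports", "pe_sunshine"):
        scaler = pe_scalers[name] if pe_scalers else ZScaler.fit(lot[name])
        lot[f"{name}_z"] = scaler.transform(lot[name])
    lot["mood_z"] = zscore(lot["mood"])

    lot = _merge_nuisance(lot, nuisance)
    return lot.reset_index(drop=True)
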