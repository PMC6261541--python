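"""Dummy-coded nuisance regressors for daily panel models.

City-level mood and gambling series carry strong cyclical structure:
day-of-week and month-of-year seasonality, holiday spikes, paycheck-day
gambling, and severe-weather disruptions.  This module builds the full
indicator matrix for those nuisance sources; reference-level dropping is
left to the model module.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
from dateutil.easter import easter

__all__ = [
    "holiday_calendar",
    "paycheck_days",
    "severe_weather_flags",
    "build_nuisance_design",
]

_DOW_NAMES = ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"]
_MONTH_NAMES = [
    "Jan", "Feb", "Mar", "Apr", "May", "Jun",
    "Jul", "Aug", "Sep", "Oct", "Nov", "Dec",
]


def _nth_weekday(year: int, month: int, weekday: int, n: int) -> dt.date:
    """n-th (1-based) given weekday (Mon=0) of a month."""
    first = dt.date(year, month, 1)
    offset = (weekday - first.weekday()) % 7
    return first + dt.timedelta(days=offset + 7 * (n - 1))


def _last_weekday(year: int, month: int, weekday: int) -> dt.date:
    nxt = dt.date(year + (month == 12), month % 12 + 1, 1)
    last = nxt - dt.timedelta(days=1)
    return last - dt.timedelta(days=(last.weekday() - weekday) % 7)


def holiday_calendar(year: int) -> list[tuple[str, dt.date]]:
    """Named days flagged as holiday regressors for one calendar year.

    Federal Monday holidays (MLK, Presidents', Memorial, Labor, Columbus)
    plus the fixed-date and movable days in the nuisance set: Jan 1 and 2,
    Valentine's Day, Easter Sunday, July 4, Veterans' Day, Thanksgiving and
    Christmas.
    """
    return [
        ("new_years_day", dt.date(year, 1, 1)),
        ("jan_2", dt.date(year, 1, 2)),
        ("mlk_day", _nth_weekday(year, 1, 0, 3)),
        ("valentines_day", dt.date(year, 2, 14)),
        ("presidents_day", _nth_weekday(year, 2, 0, 3)),
        ("easter_sunday", easter(year)),
        ("memorial_day", _last_weekday(year, 5, 0)),
        ("july_4", dt.date(year, 7, 4)),
        ("labor_day", _nth_weekday(year, 9, 0, 1)),
        ("columbus_day", _nth_weekday(year, 10, 0, 2)),
        ("veterans_day", dt.date(year, 11, 11)),
        ("thanksgiving", _nth_weekday(year, 11, 3, 4)),
        ("christmas", dt.date(year, 12, 25)),
    ]


def paycheck_days(dates) -> pd.Series:
    """Indicator for common paycheck receipt days.

    The 1st and 15th of each month are flagged; when either falls on a
    weekend the immediately preceding weekday is flagged instead (which may
    land in the prior month, e.g. Sunday Sep 1 2013 -> Friday Aug 30).
    """
    dates = pd.DatetimeIndex(dates)
    flagged: set[pd.Timestamp] = set()
    # scan one month past either edge so shifted paydays at boundaries appear
    months = pd.period_range(
        dates.min().to_period("M") - 1, dates.max().to_period("M") + 1, freq="M"
    )
    for per in months:
        for day in (1, 15):
            d = pd.Timestamp(per.year, per.month, day)
            while d.weekday() >= 5:
                d -= pd.Timedelta(days=1)
            flagged.add(d)
    return pd.Series(dates.isin(sorted(flagged)).astype(int), index=dates, name="paycheck")


def severe_weather_flags(
    daily_weather: pd.DataFrame,
    hurricane_window: tuple | None = None,
    dates=None,
) -> pd.DataFrame:
    """Blizzard and hurricane indicators.

    A blizzard day has both snowfall and mean visibility below 5 miles.
    The hurricane flag marks a supplied closed date window (e.g. Hurricane
    Sandy, Oct 29 - Nov 1 2012, for New York).
    """
    w = daily_weather.copy()
    w["date"] = pd.DatetimeIndex(pd.to_datetime(w["date"]))
    if w["date"].duplicated().any():
        raise ValueError("duplicate weather rows for a day")
    w = w.set_index("date")
    if dates is not None:
        dates = pd.DatetimeIndex(dates)
        missing = dates.difference(w.index)
        if len(missing):
            raise ValueError(f"missing weather rows for {len(missing)} requested dates")
        w = w.reindex(dates)
    idx = w.index
    blizzard = ((w["snow"].astype(int) == 1) & (w["visibility_miles"] < 5.0)).astype(int)
    out = pd.DataFrame({"blizzard": blizzard}, index=idx)
    hur = np.zeros(len(idx), dtype=int)
    if hurricane_window is not None:
        start, end = (pd.Timestamp(hurricane_window[0]), pd.Timestamp(hurricane_window[1]))
        hur = ((idx >= start) & (idx <= end)).astype(int)
    out["hurricane"] = hur
    return out


def build_nuisance_design(
    dates,
    region_flags: pd.DataFrame | None = None,
    pooled_holidays: bool = False,
    include_paycheck: bool = True,
) -> pd.DataFrame:
    """Full indicator matrix of calendar nuisance regressors.

    Seven day-of-week and twelve month columns (each row sums to one within
    either block), one column per named holiday (or a single pooled column),
    a paycheck-day column, and optional severe-weather flags joined by date.
    Reference levels are not dropped here.
    """
    dates = pd.DatetimeIndex(dates)
    if dates.duplicated().any():
        raise ValueError("duplicate dates in design request")
    cols: dict[str, np.ndarray] = {}
    dow = dates.weekday
    for i, name in enumerate(_DOW_NAMES):
        cols[f"dow_{name}"] = (dow == i).astype(int)
    month = dates.month
    for i, name in enumerate(_MONTH_NAMES, start=1):
        cols[f"month_{name}"] = (month == i).astype(int)

    years = sorted(set(dates.year))
    named: dict[str, set] = {}
    for year in years:
        for name, day in holiday_calendar(year):
            named.setdefault(name, set()).add(pd.Timestamp(day))
    if pooled_holidays:
        all_days = sorted(set().union(*named.values()))
        cols["holiday"] = dates.isin(all_days).astype(int)
    else:
        for name, days in named.items():
            cols[f"holiday_{name}"] = dates.isin(sorted(days)).astype(int)

    design = pd.DataFrame(cols, index=dates)
    if include_paycheck:
        design["paycheck"] = paycheck_days(dates).values
    if region_flags is not None:
        design = design.join(region_flags.reindex(dates).fillna(0).astype(int))
    return design
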