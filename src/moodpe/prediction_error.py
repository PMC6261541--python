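"""Exponentially weighted expectations and prediction errors.

Sports teams and daily sunshine both yield sequences of valenced outcomes.
For each sequence we maintain a recency-weighted expectation via the delta
rule

    x_bar <- x_bar + alpha * (x - x_bar)

and define the prediction error (PE) on an event day as the signed deviation
of the observed outcome from the expectation carried into that day,
``PE = x - x_bar``.  Game outcomes are coded win=1, loss=0, tie=0.5, so the
sports expectation is a winning probability and PEs live in [-1, 1]; daily
mean solar irradiance (DNI, W/m^2) is nonnegative and unbounded.

Team-level PEs are summed per day within a metropolitan statistical area
(MSA) to produce the citywide sports PE series used downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpectationParams",
    "EntityTrace",
    "CityPESeries",
    "update_expectation",
    "prediction_error",
    "entity_trace",
    "citywide_sum_pe",
    "daily_mean_irradiance",
    "sunshine_pe_series",
    "build_pe_series",
]

#: default learning rate used throughout the analyses
DEFAULT_ALPHA = 0.1


@dataclass(frozen=True)
class ExpectationParams:
    """Recency parameter and initial expectation for the delta-rule filter.

    alpha : learning rate in (0, 1]; 0.1 by default.
    p0 : expectation before any event.  ``None`` selects the mode default:
        0.5 for bounded (sports) outcomes, the first observed value for
        irradiance series.
    """

    alpha: float = DEFAULT_ALPHA
    p0: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.p0 is not None and not math.isfinite(self.p0):
            raise ValueError("p0 must be finite")


@dataclass
class EntityTrace:
    """Daily expectation trace plus event-day PEs for one entity.

    ``expectation`` is indexed by every calendar day in range and stores the
    expectation *entering* that day (carry-forward on non-event days).
    ``pe`` is indexed by event days only; a date may repeat when a team plays
    twice in one day (doubleheaders), in which case PEs appear in game order.
    """

    entity_id: str
    expectation: pd.Series
    pe: pd.Series = field(repr=False)


@dataclass
class CityPESeries:
    """Daily citywide PE sum for one MSA; 0 on days with no events."""

    msa_id: str
    pe_sum: pd.Series

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.pe_sum.index


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


def update_expectation(
    prev: float, outcome: float, params: ExpectationParams
) -> float:
    """One delta-rule step: ``prev + alpha * (outcome - prev)``."""
    prev = _check_finite("prev", prev)
    outcome = _check_finite("outcome", outcome)
    return prev + params.alpha * (outcome - prev)


def prediction_error(outcome: float, expectation: float) -> float:
    """Signed deviation of the outcome from its expectation."""
    return _check_finite("outcome", outcome) - _check_finite(
        "expectation", expectation
    )


def _normalize_calendar(calendar) -> pd.DatetimeIndex:
    calendar = pd.DatetimeIndex(calendar)
    if len(calendar) == 0:
        raise ValueError("calendar is empty")
    if not calendar.is_monotonic_increasing:
        raise ValueError("calendar must be sorted")
    return calendar


def entity_trace(
    events: pd.DataFrame,
    params: ExpectationParams,
    calendar,
    bounded: bool = True,
) -> EntityTrace:
    """Run the delta rule over one entity's dated events.

    Parameters
    ----------
    events : DataFrame with columns ``date`` and ``outcome``, sorted by date.
        Multiple rows on one date are processed in listed order (e.g. MLB
        doubleheaders), each updating the expectation in turn.
    params : filter parameters; ``p0=None`` means 0.5 when ``bounded`` else
        the first event's outcome.
    calendar : full daily date range the trace must cover.
    bounded : validate outcomes in {0, 0.5, 1} and expectations in [0, 1]
        (sports mode); irradiance mode only requires nonnegative outcomes.
    """
    calendar = _normalize_calendar(calendar)
    entity_id = str(events["entity_id"].iloc[0]) if "entity_id" in events and len(events) else ""
    dates = pd.DatetimeIndex(pd.to_datetime(events["date"])) if len(events) else pd.DatetimeIndex([])
    outcomes = np.asarray(events["outcome"], dtype=float) if len(events) else np.empty(0)

    if len(dates):
        if not dates.is_monotonic_increasing:
            raise ValueError("events must be sorted by date")
        if dates[0] < calendar[0] or dates[-1] > calendar[-1]:
            raise ValueError("event outside calendar range")
    if not np.all(np.isfinite(outcomes)):
        raise ValueError("non-finite outcome")
    if bounded:
        if not np.all(np.isin(outcomes, (0.0, 0.5, 1.0))):
            raise ValueError("sports outcomes must be 0, 0.5 or 1")
    elif np.any(outcomes < 0):
        raise ValueError("outcomes must be nonnegative")

    if params.p0 is not None:
        p = float(params.p0)
    elif bounded:
        p = 0.5
    else:
        p = float(outcomes[0]) if len(outcomes) else 0.0
    if bounded and not (0.0 <= p <= 1.0):
        raise ValueError("sports p0 must lie in [0, 1]")

    expect = np.empty(len(calendar))
    pe_dates: list[pd.Timestamp] = []
    pe_vals: list[float] = []
    pos = calendar.get_indexer(dates)
    if len(dates) and (pos < 0).any():
        raise ValueError("event date not on the daily calendar grid")
    j = 0
    for i in range(len(calendar)):
        expect[i] = p  # expectation entering this day
        while j < len(dates) and pos[j] == i:
            pe_dates.append(dates[j])
            pe_vals.append(outcomes[j] - p)
            p = update_expectation(p, outcomes[j], params)
            j += 1

    expectation = pd.Series(expect, index=calendar, name="expectation")
    pe = pd.Series(pe_vals, index=pd.DatetimeIndex(pe_dates), name="pe", dtype=float)
    return EntityTrace(entity_id=entity_id, expectation=expectation, pe=pe)


def citywide_sum_pe(
    traces: list[pd.Series | EntityTrace], msa_id: str, calendar
) -> CityPESeries:
    """Sum event-day PEs over an MSA's teams; no-game days contribute 0."""
    calendar = _normalize_calendar(calendar)
    series = [t.pe if isinstance(t, EntityTrace) else t for t in traces]
    for s in series:
        if len(s) and (s.index.min() < calendar[0] or s.index.max() > calendar[-1]):
            raise ValueError("PE series extends outside the shared calendar")
    if series:
        pooled = pd.concat(series)
        daily = pooled.groupby(level=0).sum()
    else:
        daily = pd.Series(dtype=float)
    pe_sum = daily.reindex(calendar, fill_value=0.0).astype(float)
    pe_sum.name = "pe_sum"
    return CityPESeries(msa_id=msa_id, pe_sum=pe_sum)


def build_pe_series(
    games: pd.DataFrame,
    irradiance: pd.DataFrame,
    calendar,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[dict[str, CityPESeries], dict[str, CityPESeries]]:
    """Citywide sports and sunshine PE series per MSA from raw tables.

    Sports: one delta-rule trace per team, event-day PEs summed citywide.
    Sunshine: hourly DNI collapsed to daily means, then traced with an event
    every day; its "citywide" series is just that daily PE series.
    """
    params = ExpectationParams(alpha=alpha)
    pe_sports: dict[str, CityPESeries] = {}
    for msa, sub in games.groupby("msa_id"):
        traces = [
            entity_trace(team_games, params, calendar, bounded=True)
            for _, team_games in sub.groupby("team_id")
        ]
        pe_sports[str(msa)] = citywide_sum_pe(traces, str(msa), calendar)
    pe_sun: dict[str, CityPESeries] = {}
    for msa, sub in irradiance.groupby("msa_id"):
        daily = daily_mean_irradiance(sub)
        trace = sunshine_pe_series(daily, params)
        pe_sun[str(msa)] = CityPESeries(msa_id=str(msa), pe_sum=trace.pe)
    return pe_sports, pe_sun


def daily_mean_irradiance(hourly: pd.DataFrame) -> pd.DataFrame:
    """Collapse hourly DNI to a daily mean over strictly positive hours.

    Night hours report zero irradiance and are excluded from the mean; a day
    whose hours are all zero (fully overcast in the satellite retrieval)
    yields 0 rather than missing.
    """
    dni = np.asarray(hourly["dni_wm2"], dtype=float)
    if np.any(dni < 0):
        raise ValueError("dni_wm2 must be nonnegative")
    day = pd.to_datetime(hourly["timestamp"]).dt.normalize()

    def _mean_nonzero(x: pd.Series) -> float:
        pos = x[x > 0]
        return float(pos.mean()) if len(pos) else 0.0

    daily = (
        pd.Series(dni, index=hourly.index)
        .groupby(day.values)
        .agg(_mean_nonzero)
        .rename("outcome")
    )
    out = daily.reset_index().rename(columns={"index": "date"})
    out["date"] = pd.DatetimeIndex(out["date"])
    return out


def sunshine_pe_series(
    daily: pd.DataFrame, params: ExpectationParams
) -> EntityTrace:
    """Delta-rule trace over a contiguous daily irradiance series.

    Every day is an event day, so the PE series is defined on the full
    calendar.  Gaps in the daily grid are rejected rather than silently
    filled.
    """
    dates = pd.DatetimeIndex(pd.to_datetime(daily["date"]))
    if len(dates) == 0:
        raise ValueError("empty daily series")
    full = pd.date_range(dates[0], dates[-1], freq="D")
    if len(full) != len(dates) or not (full == dates).all():
        raise ValueError("daily irradiance series has gaps; fill explicitly")
    return entity_trace(daily, params, calendar=full, bounded=False)
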