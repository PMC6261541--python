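"""End-to-end orchestration: PE construction -> panels -> fits -> mediation.

Stages run in a fixed order on the interchange tables in ``data_dir`` and
write every artifact (pe.csv, panels, fit JSONs, mediation JSONs, run log)
into an output directory.  Deterministic stages are bitwise reproducible for
a fixed config; the mediation stage is seeded from the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import io
from .calendar_design import build_nuisance_design, severe_weather_flags
from .config import PipelineConfig
from .mediation import mediate
from .panel_builder import build_gambling_panel, build_mood_panel
from .panel_model import ModelSpec, fit_mixed
from .prediction_error import build_pe_series

__all__ = ["run_pipeline", "pe_table", "nuisance_for"]

log = logging.getLogger("moodpe")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and input summary."""


def _stage(name: str, func, *args, **kwargs):
    try:
        return func(*args, **kwargs)
    except Exception as err:
        raise StageError(f"stage {name!r} failed: {err}") from err


def pe_table(pe_sports: dict, pe_sunshine: dict) -> pd.DataFrame:
    """Long-format citywide PE series for pe.csv."""
    rows = []
    for series, mapping in (("sports", pe_sports), ("sunshine", pe_sunshine)):
        for msa, city in mapping.items():
            rows.append(pd.DataFrame({
                "date": city.pe_sum.index,
                "msa_id": msa,
                "series": series,
                "pe": city.pe_sum.values,
            }))
    return pd.concat(rows, ignore_index=True)


def nuisance_for(calendar, weather: pd.DataFrame | None, cfg: PipelineConfig) -> pd.DataFrame:
    """Calendar design, replicated per MSA with its severe-weather flags."""
    base = build_nuisance_design(calendar, pooled_holidays=cfg.pooled_holidays)
    if weather is None or not cfg.use_weather_flags:
        return base
    frames = []
    for msa, sub in weather.groupby("msa_id"):
        flags = severe_weather_flags(
            sub.drop(columns="msa_id"),
            hurricane_window=tuple(cfg.hurricane_window) if cfg.hurricane_window else None,
            dates=calendar,
        )
        block = base.join(flags)
        block = block.reset_index(names="date")
        block.insert(0, "msa_id", str(msa))
        frames.append(block)
    return pd.concat(frames, ignore_index=True)


def _nuisance_columns(nuisance: pd.DataFrame, include_paycheck: bool) -> list[str]:
    cols = [c for c in nuisance.columns if c not in ("msa_id", "date")]
    if not include_paycheck:
        cols = [c for c in cols if c != "paycheck"]
    return cols


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and return a summary dict (also written as run_log)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = Path(cfg.data_dir)

    tables = {}
    for name in ("games", "irradiance", "sentiment", "lottery", "population", "geography"):
        tables[name] = _stage(f"read:{name}", io.read_table, data / f"{name}.csv", name)
        log.info("read %s: %d rows", name, len(tables[name]))
    weather_path = data / "weather.csv"
    weather = io.read_table(weather_path, "weather") if weather_path.exists() else None

    dates = tables["sentiment"]["date"]
    calendar = pd.date_range(dates.min(), dates.max(), freq="D")

    pe_sports, pe_sun = _stage(
        "pe", build_pe_series, tables["games"], tables["irradiance"], calendar, cfg.alpha
    )
    io.write_table(pe_table(pe_sports, pe_sun), outdir / "pe.csv")

    nuisance = nuisance_for(calendar, weather, cfg)
    nuis_mood = _nuisance_columns(nuisance, include_paycheck=False)
    nuis_gamb = _nuisance_columns(nuisance, include_paycheck=True)

    mood_panel, scalers = _stage(
        "panel:mood", build_mood_panel,
        tables["sentiment"], pe_sports, pe_sun, tables["population"], nuisance,
        calendar, cfg.min_tweets, cfg.min_frac, cfg.sports_lag, cfg.sunshine_lag,
    )
    gamb_panel = _stage(
        "panel:gambling", build_gambling_panel,
        tables["lottery"], mood_panel, tables["geography"], pe_sports, pe_sun,
        tables["population"], nuisance, scalers,
        cfg.min_pop, cfg.sports_lag, cfg.sunshine_lag, cfg.log_eps,
    )
    io.write_table(mood_panel, outdir / "panel_mood.csv")
    io.write_table(gamb_panel, outdir / "panel_gambling.csv")

    n_gamb_msas = gamb_panel["msa_id"].nunique()
    fits = {}
    specs = {
        "mood_sports": ModelSpec("mood", ["pe_sports_z"], nuis_mood, reml=cfg.reml),
        "mood_sunshine": ModelSpec("mood", ["pe_sunshine_z"], nuis_mood, reml=cfg.reml),
        "gambling_mood": ModelSpec(
            "log_per_capita", ["mood_z"], nuis_gamb,
            group_msa="msa_id" if n_gamb_msas >= 2 else None,
            group_unit="postal_code", reml=cfg.reml,
        ),
        "gambling_sports": ModelSpec(
            "log_per_capita", ["pe_sports_z"], nuis_gamb,
            group_msa="msa_id" if n_gamb_msas >= 2 else None,
            group_unit="postal_code", reml=cfg.reml,
        ),
        "gambling_sunshine": ModelSpec(
            "log_per_capita", ["pe_sunshine_z"], nuis_gamb,
            group_msa="msa_id" if n_gamb_msas >= 2 else None,
            group_unit="postal_code", reml=cfg.reml,
        ),
        # outcome models for mediation: treatment + raw mood mediator
        "gambling_sports_mood": ModelSpec(
            "log_per_capita", ["pe_sports_z", "mood"], nuis_gamb,
            group_msa="msa_id" if n_gamb_msas >= 2 else None,
            group_unit="postal_code", reml=cfg.reml,
        ),
        "gambling_sunshine_mood": ModelSpec(
            "log_per_capita", ["pe_sunshine_z", "mood"], nuis_gamb,
            group_msa="msa_id" if n_gamb_msas >= 2 else None,
            group_unit="postal_code", reml=cfg.reml,
        ),
    }
    for name, spec in specs.items():
        panel = mood_panel if name.startswith("mood") else gamb_panel
        fits[name] = _stage(f"fit:{name}", fit_mixed, panel, spec)
        io.write_json(fits[name].to_dict(), outdir / f"fit_{name}.json")
        log.info("fit %s: n=%d beta=%s", name, fits[name].n_obs,
                 fits[name].beta[spec.predictors].to_dict())

    mediations = {}
    for source in ("sports", "sunshine"):
        res = _stage(
            f"mediate:{source}", mediate,
            fits[f"mood_{source}"], fits[f"gambling_{source}_mood"],
            f"pe_{source}_z", "mood", cfg.n_sims, cfg.seed,
        )
        mediations[source] = res
        io.write_json(res.to_dict(), outdir / f"mediation_{source}.json")

    cfg_dict = cfg.to_dict()
    run_log = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "rows_in": {k: int(len(v)) for k, v in tables.items()},
        "counties_retained": sorted(mood_panel["county_id"].astype(str).unique()),
        "postal_retained": sorted(gamb_panel["postal_code"].astype(str).unique()),
        "n_obs": {
            "mood_panel": int(len(mood_panel)),
            "gambling_panel": int(len(gamb_panel)),
        },
        "fits": {k: {"beta": v.beta.to_dict(), "r2_conditional": v.r2_conditional}
                 for k, v in fits.items()},
        "mediation": {k: v.to_dict() for k, v in mediations.items()},
    }
    io.write_json(run_log, outdir / "run_log.json")
    return run_log
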