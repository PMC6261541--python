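"""Parameter-recovery and mediation-calibration experiments.

These routines run the full chain — simulate, construct prediction errors,
assemble panels, fit the weighted nested mixed models — against the
generator's known ground truth.  They back both the test suite and the
acceptance script, so the numbers those report are always recomputed from
scratch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import PipelineConfig
from .panel_builder import build_gambling_panel, build_mood_panel
from .panel_model import ModelSpec, fit_mixed
from .pipeline import nuisance_for
from .prediction_error import build_pe_series
from .synthetic_data import SimConfig, simulate

__all__ = ["recovery_replicate", "linear_mediation_fits", "end_to_end_run"]


def end_to_end_run(sim_config: SimConfig, n_sims: int = 10_000, seed: int | None = None):
    """simulate -> PE -> panels -> fits -> mediation, all in memory.

    Returns (fits, mediations, truth, panels).
    """
    from .mediation import mediate

    tables, truth = simulate(sim_config)
    cfg = PipelineConfig(alpha=sim_config.alpha,
                         n_sims=n_sims,
                         seed=sim_config.seed if seed is None else seed)
    calendar = sim_config.calendar
    pe_sports, pe_sun = build_pe_series(
        tables["games"], tables["irradiance"], calendar, cfg.alpha
    )
    nuisance = nuisance_for(calendar, tables["weather"], cfg)
    mood_panel, scalers = build_mood_panel(
        tables["sentiment"], pe_sports, pe_sun, tables["population"], nuisance,
        calendar, cfg.min_tweets, cfg.min_frac, cfg.sports_lag, cfg.sunshine_lag,
    )
    gamb_panel = build_gambling_panel(
        tables["lottery"], mood_panel, tables["geography"], pe_sports, pe_sun,
        tables["population"], nuisance, scalers,
        cfg.min_pop, cfg.sports_lag, cfg.sunshine_lag, cfg.log_eps,
    )
    nuis = [c for c in nuisance.columns if c not in ("msa_id", "date")]
    nuis_mood = [c for c in nuis if c != "paycheck"]
    n_gm = gamb_panel["msa_id"].nunique()
    g_msa = "msa_id" if n_gm >= 2 else None
    fits = {
        "mood_sports": fit_mixed(mood_panel, ModelSpec(
            "mood", ["pe_sports_z"], nuis_mood)),
        "mood_sunshine": fit_mixed(mood_panel, ModelSpec(
            "mood", ["pe_sunshine_z"], nuis_mood)),
        "gambling_mood": fit_mixed(gamb_panel, ModelSpec(
            "log_per_capita", ["mood_z"], nuis,
            group_msa=g_msa, group_unit="postal_code")),
        "gambling_sports_mood": fit_mixed(gamb_panel, ModelSpec(
            "log_per_capita", ["pe_sports_z", "mood"], nuis,
            group_msa=g_msa, group_unit="postal_code")),
    }
    mediations = {
        "sports": mediate(fits["mood_sports"], fits["gambling_sports_mood"],
                          "pe_sports_z", "mood", n_sims=cfg.n_sims, seed=cfg.seed),
    }
    panels = {"mood": mood_panel, "gambling": gamb_panel}
    return fits, mediations, truth, panels


def recovery_replicate(seed: int, **overrides) -> dict:
    """One end-to-end replicate: estimates, SEs and CI coverage vs truth.

    Fits only the two models the recovery experiment scores (lagged sports
    PE -> mood; standardized mood -> log per-capita gambling).
    """
    cfg = SimConfig(seed=seed, **overrides)
    tables, truth = simulate(cfg)
    pcfg = PipelineConfig(alpha=cfg.alpha)
    calendar = cfg.calendar
    pe_sports, pe_sun = build_pe_series(
        tables["games"], tables["irradiance"], calendar, cfg.alpha
    )
    nuisance = nuisance_for(calendar, tables["weather"], pcfg)
    mood_panel, scalers = build_mood_panel(
        tables["sentiment"], pe_sports, pe_sun, tables["population"], nuisance,
        calendar,
    )
    gamb_panel = build_gambling_panel(
        tables["lottery"], mood_panel, tables["geography"], pe_sports, pe_sun,
        tables["population"], nuisance, scalers,
    )
    nuis = [c for c in nuisance.columns if c not in ("msa_id", "date")]
    nuis_mood = [c for c in nuis if c != "paycheck"]
    mood_fit = fit_mixed(mood_panel, ModelSpec("mood", ["pe_sports_z"], nuis_mood))
    # fully specified outcome model: both PE paths plus the mediator, so the
    # generating coefficients are identified without omitted-variable bias
    gamb_fit = fit_mixed(gamb_panel, ModelSpec(
        "log_per_capita", ["pe_sports_z", "pe_sunshine_z", "mood_z"], nuis,
        group_msa="msa_id" if gamb_panel["msa_id"].nunique() >= 2 else None,
        group_unit="postal_code"))

    out = {}
    for tag, fit, coef, true_val in (
        ("mood", mood_fit, "pe_sports_z", truth["mood"]["beta_pe_mood"]),
        ("gambling", gamb_fit, "mood_z", truth["gambling"]["beta_mood_gambling"]),
    ):
        est, se = float(fit.beta[coef]), float(fit.se[coef])
        out[tag] = {
            "estimate": est,
            "se": se,
            "truth": true_val,
            "covered": bool(est - 1.959964 * se <= true_val <= est + 1.959964 * se),
            "n_obs": fit.n_obs,
        }
    return out


def linear_mediation_fits(
    seed: int, n: int = 20_000, a: float = 0.5, b: float = 0.4, c_prime: float = 0.3
):
    """Linear Gaussian treatment -> mediator -> outcome dataset, OLS fits.

    Unit-variance noise on both equations; returns (mediator_fit,
    outcome_fit) as statsmodels OLS results.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    m = a * x + rng.standard_normal(n)
    y = c_prime * x + b * m + rng.standard_normal(n)
    X = pd.DataFrame({"Intercept": np.ones(n), "x": x})
    med = sm.OLS(m, X).fit()
    out = sm.OLS(y, X.assign(m=m)).fit()
    return med, out
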