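"""Simulation-based causal mediation for the PE -> mood -> gambling chain.

Given a fitted mediator model (mood regressed on a prediction-error
treatment plus nuisance terms) and a fitted outcome model (log per-capita
gambling on the treatment, the mediator, and nuisance terms), the average
causal mediation effect (ACME), average direct effect (ADE), total effect,
and proportion mediated are estimated by a quasi-Bayesian Monte Carlo
procedure: parameter vectors are drawn from the multivariate-normal
approximation to each model's sampling distribution and the effects are
computed per draw.  With linear models and no treatment-mediator
interaction the per-draw effects reduce to

    ACME = a * b,   ADE = c',   total = a * b + c',

where a is the treatment coefficient in the mediator model and b, c' are
the mediator and treatment coefficients in the outcome model.  Confidence
intervals are percentile intervals over draws and p-values are two-sided
sign-crossing frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel_model import MixedModelFit

__all__ = ["FixedEffects", "MediationResult", "mediate", "proportion_mediated"]


@dataclass
class FixedEffects:
    """Coefficient vector and covariance of any fitted linear model."""

    params: pd.Series
    cov: pd.DataFrame

    @classmethod
    def from_fit(cls, fit) -> "FixedEffects":
        if isinstance(fit, FixedEffects):
            return fit
        if isinstance(fit, MixedModelFit):
            return cls(params=fit.beta, cov=fit.cov_fe)
        # statsmodels results expose .params / .cov_params()
        if hasattr(fit, "params") and hasattr(fit, "cov_params"):
            cov = fit.cov_params()
            return cls(params=pd.Series(fit.params), cov=pd.DataFrame(cov))
        raise TypeError(f"cannot extract fixed effects from {type(fit)!r}")


@dataclass
class MediationResult:
    acme: float
    ade: float
    total: float
    prop_mediated: float
    ci: dict[str, tuple[float, float]]
    pvalues: dict[str, float]
    n_sims: int
    seed: int
    conf_level: float

    def to_dict(self) -> dict:
        return {
            "acme": self.acme,
            "ade": self.ade,
            "total": self.total,
            "prop_mediated": self.prop_mediated,
            "prop_mediated_pct": 100.0 * self.prop_mediated,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "pvalues": self.pvalues,
            "n_sims": self.n_sims,
            "seed": self.seed,
            "conf_level": self.conf_level,
        }


def proportion_mediated(acme: float, total: float) -> float:
    """ACME as a percentage of the total effect; undefined at total = 0.

    Values outside [0, 100] signal inconsistent mediation (opposing signs of
    the indirect and direct paths) and are returned as-is.
    """
    if total == 0:
        raise ZeroDivisionError("total effect is zero; proportion mediated undefined")
    return 100.0 * acme / total


def _draws(fe: FixedEffects, rng: np.random.Generator, n: int) -> pd.DataFrame:
    cov = fe.cov.to_numpy(dtype=float)
    cov = 0.5 * (cov + cov.T)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError("parameter covariance is not positive definite") from err
    z = rng.standard_normal((n, cov.shape[0]))
    sims = fe.params.to_numpy(dtype=float)[None, :] + z @ L.T
    return pd.DataFrame(sims, columns=fe.params.index)


def _two_sided_p(draws: np.ndarray) -> float:
    pos = float(np.mean(draws > 0))
    neg = float(np.mean(draws < 0))
    return min(1.0, 2.0 * min(pos, neg))


def mediate(
    mediator_fit,
    outcome_fit,
    treatment: str,
    mediator: str,
    n_sims: int = 10_000,
    seed: int = 17,
    conf_level: float = 0.95,
) -> MediationResult:
    """Quasi-Bayesian Monte Carlo mediation estimate.

    The mediator must be named identically (and measured on the same scale)
    in the mediator model's outcome and the outcome model's predictors; the
    treatment must appear in both models.  Deterministic given ``seed`` and
    ``n_sims``.
    """
    if n_sims < 1000:
        raise ValueError("n_sims must be at least 1000")
    med = FixedEffects.from_fit(mediator_fit)
    out = FixedEffects.from_fit(outcome_fit)
    if treatment not in med.params.index or treatment not in out.params.index:
        raise KeyError(f"treatment {treatment!r} must appear in both fits")
    if mediator not in out.params.index:
        raise KeyError(f"mediator {mediator!r} must appear in the outcome fit")
    if mediator in med.params.index:
        raise KeyError(f"mediator {mediator!r} cannot be a predictor of itself")

    rng = np.random.default_rng(seed)
    a = _draws(med, rng, n_sims)[treatment].to_numpy()
    out_draws = _draws(out, rng, n_sims)
    b = out_draws[mediator].to_numpy()
    c_prime = out_draws[treatment].to_numpy()

    acme_d = a * b
    ade_d = c_prime
    total_d = acme_d + ade_d

    lo, hi = 50 * (1 - conf_level), 50 * (1 + conf_level)
    ci = {
        name: (float(np.percentile(d, lo)), float(np.percentile(d, hi)))
        for name, d in (("acme", acme_d), ("ade", ade_d), ("total", total_d))
    }
    pvalues = {
        "acme": _two_sided_p(acme_d),
        "ade": _two_sided_p(ade_d),
        "total": _two_sided_p(total_d),
    }

    acme = float(np.mean(acme_d))
    ade = float(np.mean(ade_d))
    total = float(np.mean(total_d))
    with np.errstate(divide="ignore", invalid="ignore"):
        prop_d = np.where(total_d != 0, acme_d / total_d, np.nan)
    prop = acme / total if total != 0 else float("nan")
    ci["prop_mediated"] = (
        float(np.nanpercentile(prop_d, lo)),
        float(np.nanpercentile(prop_d, hi)),
    )

    return MediationResult(
        acme=acme,
        ade=ade,
        total=total,
        prop_mediated=prop,
        ci=ci,
        pvalues=pvalues,
        n_sims=n_sims,
        seed=seed,
        conf_level=conf_level,
    )
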