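"""Population-weighted linear mixed-effects panel models.

The mood and gambling regressions are Gaussian mixed models with nested
random intercepts (MSA, and county or postal code within MSA), fixed effects
for the z-scored predictors of interest plus the calendar nuisance set, and
unit populations as precision ("sample") weights:

    y = X beta + Z_msa u + Z_unit v + e,
    u ~ N(0, s2_msa I),  v ~ N(0, s2_unit I),  e_i ~ N(0, s2_e / w_i).

Estimation profiles beta and the residual scale out of the (restricted)
likelihood and optimizes only the variance ratios lambda_g = s2_g / s2_e.
Because the random-effects design consists of group indicators, all
likelihood terms reduce — via the Woodbury identity — to fixed moment
matrices (U'WU, U'WX, X'WX, ...) computed once, so each evaluation costs
O(q^3 + q^2 p) with q the total number of random intercepts.

Model fit is summarized by the Nakagawa–Schielzeth marginal and conditional
R^2 for Gaussian responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats

__all__ = [
    "ModelSpec",
    "MixedModelFit",
    "fit_mixed",
    "conditional_r2",
    "marginal_r2",
    "residualize",
    "intercounty_correlation",
]

DEFAULT_REFERENCE_LEVELS = ("dow_Sun", "month_Jan")


@dataclass
class ModelSpec:
    """What to regress on what, and how rows group and weigh.

    ``group_msa``/``group_unit`` name the nesting columns; either may be
    ``None`` to drop that random-intercept level.  ``weights`` names a
    positive population column treated as precision weights, or ``None`` for
    an unweighted fit.  Reference levels listed in ``drop_reference`` are
    removed from the nuisance set to keep the design full rank alongside the
    intercept.
    """

    outcome: str
    predictors: list[str]
    nuisance: list[str] = field(default_factory=list)
    group_msa: str | None = "msa_id"
    group_unit: str | None = "county_id"
    weights: str | None = "weight"
    reml: bool = True
    drop_reference: tuple = DEFAULT_REFERENCE_LEVELS

    def __post_init__(self) -> None:
        overlap = set(self.predictors) & set(self.nuisance)
        if overlap:
            raise ValueError(f"predictors duplicated in nuisance set: {sorted(overlap)}")


@dataclass
class MixedModelFit:
    """Fixed effects, variance components and fit metadata."""

    beta: pd.Series
    se: pd.Series
    pvalues: pd.Series
    cov_fe: pd.DataFrame
    var_msa: float
    var_unit: float
    var_resid: float
    var_fixed: float
    n_obs: int
    n_groups: dict[str, int]
    converged: bool
    method: str
    loglik: float

    @property
    def r2_conditional(self) -> float:
        return conditional_r2(self)

    @property
    def r2_marginal(self) -> float:
        return marginal_r2(self)

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.to_dict(),
            "se": self.se.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "cov_fe": {"columns": list(self.cov_fe.columns), "values": self.cov_fe.values.tolist()},
            "var_msa": self.var_msa,
            "var_unit": self.var_unit,
            "var_resid": self.var_resid,
            "var_fixed": self.var_fixed,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "converged": self.converged,
            "method": self.method,
            "loglik": self.loglik,
            "r2_conditional": self.r2_conditional,
            "r2_marginal": self.r2_marginal,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixedModelFit":
        cols = d["cov_fe"]["columns"]
        return cls(
            beta=pd.Series(d["beta"]),
            se=pd.Series(d["se"]),
            pvalues=pd.Series(d["pvalues"]),
            cov_fe=pd.DataFrame(d["cov_fe"]["values"], index=cols, columns=cols),
            var_msa=d["var_msa"],
            var_unit=d["var_unit"],
            var_resid=d["var_resid"],
            var_fixed=d["var_fixed"],
            n_obs=d["n_obs"],
            n_groups=d["n_groups"],
            converged=d["converged"],
            method=d["method"],
            loglik=d["loglik"],
        )


def conditional_r2(fit: MixedModelFit) -> float:
    """Share of variance captured by fixed and random effects jointly."""
    num = fit.var_fixed + fit.var_msa + fit.var_unit
    total = num + fit.var_resid
    if total <= 0:
        raise ValueError("total variance is zero; R^2 undefined")
    return num / total


def marginal_r2(fit: MixedModelFit) -> float:
    """Share of variance captured by the fixed effects alone."""
    total = fit.var_fixed + fit.var_msa + fit.var_unit + fit.var_resid
    if total <= 0:
        raise ValueError("total variance is zero; R^2 undefined")
    return fit.var_fixed / total


def _group_indicator(labels: np.ndarray) -> tuple[sparse.csr_matrix, int]:
    codes, uniques = pd.factorize(labels, sort=True)
    n, q = len(codes), len(uniques)
    Z = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, q)
    )
    return Z, q


class _ProfiledLMM:
    """Profiled deviance of the weighted nested random-intercept model."""

    def __init__(self, y, X, w, group_labels: list[np.ndarray], reml: bool):
        self.n, self.p = X.shape
        self.reml = reml
        W = w
        blocks = []
        self.level_sizes = []
        for labels in group_labels:
            Z, q = _group_indicator(np.asarray(labels))
            blocks.append(Z)
            self.level_sizes.append(q)
        self.q = int(sum(self.level_sizes))
        if blocks:
            U = sparse.hstack(blocks, format="csr")
            UW = U.multiply(W[:, None]).tocsr()
            self.G = np.asarray((UW.T @ U).todense())      # U'WU
            self.H = np.asarray(UW.T @ X)                  # U'WX
            self.g = np.asarray(UW.T @ y).ravel()          # U'Wy
        else:
            self.G = np.zeros((0, 0))
            self.H = np.zeros((0, self.p))
            self.g = np.zeros(0)
        self.XtWX = X.T @ (W[:, None] * X)
        self.XtWy = X.T @ (W * y)
        self.ytWy = float(y @ (W * y))
        self.sumlogw = float(np.sum(np.log(W)))

    def _svec(self, s: np.ndarray) -> np.ndarray:
        return np.repeat(np.asarray(s, dtype=float), self.level_sizes)

    def _solve(self, s: np.ndarray):
        """Return (beta, quad, logdetV0, XtViX) at scale-ratios sqrt(lambda)=s."""
        if self.q:
            sv = self._svec(s)
            A = np.eye(self.q) + (sv[:, None] * self.G) * sv[None, :]
            cho = np.linalg.cholesky(A)
            logdetA = 2.0 * np.sum(np.log(np.diag(cho)))
            SH = sv[:, None] * self.H
            Sg = sv * self.g
            t_H = np.linalg.solve(A, SH)
            t_g = np.linalg.solve(A, Sg)
            XtViX = self.XtWX - SH.T @ t_H
            XtViy = self.XtWy - SH.T @ t_g
            ytViy = self.ytWy - Sg @ t_g
        else:
            logdetA = 0.0
            XtViX, XtViy, ytViy = self.XtWX, self.XtWy, self.ytWy
        beta = np.linalg.solve(XtViX, XtViy)
        quad = max(ytViy - beta @ XtViy, 1e-300)
        logdetV0 = logdetA - self.sumlogw
        return beta, quad, logdetV0, XtViX

    def deviance(self, s: np.ndarray) -> float:
        try:
            _, quad, logdetV0, XtViX = self._solve(s)
        except np.linalg.LinAlgError:
            return np.inf
        n, p = self.n, self.p
        if self.reml:
            df = n - p
            sign, logdetX = np.linalg.slogdet(XtViX)
            if sign <= 0:
                return np.inf
            return df * np.log(2.0 * np.pi * quad / df) + df + logdetV0 + logdetX
        return n * np.log(2.0 * np.pi * quad / n) + n + logdetV0


def _build_design(
    panel: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.DataFrame, list[str]]:
    nuisance = [c for c in spec.nuisance if c not in spec.drop_reference]
    cols = list(spec.predictors) + nuisance
    missing = [c for c in cols + [spec.outcome] if c not in panel.columns]
    if missing:
        raise ValueError(f"panel lacks columns: {missing}")
    X = panel[cols].astype(float)
    # nuisance indicators absent from the period carry no information
    degenerate = [c for c in nuisance if X[c].nunique() <= 1]
    X = X.drop(columns=degenerate)
    X.insert(0, "Intercept", 1.0)
    return X, list(X.columns)


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = [names[i] for i in np.where(diag < tol)[0]]
    if bad:
        raise ValueError(f"rank-deficient design; offending columns: {bad}")


def fit_mixed(panel: pd.DataFrame, spec: ModelSpec) -> MixedModelFit:
    """Fit the weighted nested random-intercept model by (RE)ML.

    Variance ratios are optimized on the sqrt scale with a nonnegativity
    bound, so boundary (zero-variance) solutions are admissible; a fit that
    stops at the optimizer's limits is flagged ``converged=False`` rather
    than raised.  Fixed-effect p-values use the normal approximation to the
    Wald statistic.
    """
    levels: list[tuple[str, str]] = []
    for name, col in (("msa", spec.group_msa), ("unit", spec.group_unit)):
        if col is not None:
            if col not in panel.columns:
                raise ValueError(f"grouping column {col!r} not in panel")
            levels.append((name, col))

    unit_col = spec.group_unit or spec.group_msa
    if unit_col is not None and panel.duplicated([unit_col, "date"]).any() and "date" in panel.columns:
        raise ValueError("duplicated (unit, date) rows in panel")

    X_df, names = _build_design(panel, spec)
    used = [spec.outcome] + [c for c in X_df.columns if c != "Intercept"]
    used += [col for _, col in levels]
    if spec.weights is not None:
        used.append(spec.weights)
    rows = panel[used].dropna().index
    panel = panel.loc[rows]
    X = X_df.loc[rows].to_numpy(dtype=float)
    y = panel[spec.outcome].to_numpy(dtype=float)
    _check_full_rank(X, names)

    if spec.weights is not None:
        w = panel[spec.weights].to_numpy(dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        w = w / w.mean()  # scale-free: estimates invariant to rescaling
    else:
        w = np.ones(len(y))

    group_labels = []
    n_groups: dict[str, int] = {}
    for name, col in levels:
        labels = panel[col].astype(str).to_numpy()
        n_groups[name] = len(np.unique(labels))
        if n_groups[name] < 2:
            raise ValueError(f"need >= 2 groups at level {name!r}; drop the level instead")
        group_labels.append(labels)

    lmm = _ProfiledLMM(y, X, w, group_labels, reml=spec.reml)

    k = len(group_labels)
    converged = True
    if k:
        best = None
        for x0 in (np.full(k, 0.5), np.full(k, 0.05)):
            res = optimize.minimize(
                lmm.deviance,
                x0,
                method="L-BFGS-B",
                bounds=[(0.0, None)] * k,
                options={"maxiter": 200},
            )
            if best is None or res.fun < best.fun:
                best = res
        s_hat = np.abs(best.x)
        converged = bool(best.success and np.isfinite(best.fun))
    else:
        s_hat = np.zeros(0)

    beta, quad, _, XtViX = lmm._solve(s_hat)
    df = lmm.n - lmm.p if spec.reml else lmm.n
    sigma2 = quad / df
    lam = dict(zip([name for name, _ in levels], s_hat**2))
    var_msa = lam.get("msa", 0.0) * sigma2
    var_unit = lam.get("unit", 0.0) * sigma2
    cov = sigma2 * np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    var_fixed = float(np.var(X @ beta))
    loglik = -0.5 * lmm.deviance(s_hat)

    return MixedModelFit(
        beta=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        pvalues=pd.Series(pvals, index=names),
        cov_fe=pd.DataFrame(cov, index=names, columns=names),
        var_msa=float(var_msa),
        var_unit=float(var_unit),
        var_resid=float(sigma2),
        var_fixed=var_fixed,
        n_obs=int(lmm.n),
        n_groups=n_groups,
        converged=converged,
        method="REML" if spec.reml else "ML",
        loglik=float(loglik),
    )


def residualize(
    panel: pd.DataFrame,
    outcome: str,
    nuisance: list[str],
    weights: str | None = None,
    by: str | None = "county_id",
    drop_reference: tuple = DEFAULT_REFERENCE_LEVELS,
) -> pd.Series:
    """Remove calendar nuisance structure from a series by weighted OLS.

    Fit is per group of ``by`` (or pooled when ``None``); residuals come
    back aligned to the panel index with mean ~0 within each fit.
    """
    cols = [c for c in nuisance if c not in drop_reference]
    out = pd.Series(np.nan, index=panel.index, name=f"{outcome}_resid")
    groups = panel.groupby(by).groups.values() if by is not None else [panel.index]
    for idx in groups:
        sub = panel.loc[idx]
        X = sub[cols].astype(float)
        X = X.loc[:, X.nunique() > 1]
        names = ["Intercept"] + list(X.columns)
        M = np.column_stack([np.ones(len(sub)), X.to_numpy(dtype=float)])
        if weights is not None:
            sw = np.sqrt(sub[weights].to_numpy(dtype=float))
            Mw, yw = M * sw[:, None], sub[outcome].to_numpy(dtype=float) * sw
        else:
            Mw, yw = M, sub[outcome].to_numpy(dtype=float)
        coef, _, rank, _ = np.linalg.lstsq(Mw, yw, rcond=None)
        if rank < M.shape[1]:
            _check_full_rank(Mw, names)  # raises with the offending columns
        out.loc[idx] = sub[outcome].to_numpy(dtype=float) - M @ coef
    return out


def intercounty_correlation(residuals: pd.DataFrame) -> float:
    """Mean pairwise Pearson correlation between county residual series.

    ``residuals`` is wide (one column per county, indexed by date) or long
    with columns county_id/date/resid.  Pairs sharing fewer than 2 dates are
    skipped with a warning.
    """
    if {"county_id", "date"}.issubset(residuals.columns):
        value_col = [c for c in residuals.columns if c not in ("county_id", "date")][0]
        wide = residuals.pivot(index="date", columns="county_id", values=value_col)
    else:
        wide = residuals
    counties = list(wide.columns)
    if len(counties) < 2:
        raise ValueError("need at least 2 counties")
    rs = []
    for a, b in combinations(counties, 2):
        pair = wide[[a, b]].dropna()
        if len(pair) < 2:
            warnings.warn(f"skipping pair ({a}, {b}): <2 overlapping days")
            continue
        rs.append(stats.pearsonr(pair[a], pair[b])[0])
    if not rs:
        raise ValueError("no county pair had overlapping dates")
    return float(np.mean(rs))
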