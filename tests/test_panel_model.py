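"""Weighted nested mixed models: estimates, R^2, residualization."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

from moodpe.panel_model import (
    MixedModelFit,
    ModelSpec,
    conditional_r2,
    fit_mixed,
    intercounty_correlation,
    marginal_r2,
    residualize,
)


def _one_level_panel(rng, n_groups=12, per=15, sd_u=0.8, sd_e=1.0, beta=0.5):
    g = np.repeat(np.arange(n_groups), per)
    x = rng.normal(size=n_groups * per)
    u = rng.normal(0, sd_u, n_groups)
    y = 1.0 + beta * x + u[g] + rng.normal(0, sd_e, n_groups * per)
    return pd.DataFrame({
        "y": y, "x": x, "unit": g.astype(str),
        "date": np.tile(np.arange(per), n_groups),
        "w": rng.uniform(0.5, 2.0, n_groups * per),
    })


def _nested_panel(rng, n_msa=5, per_msa=4, days=80, beta=0.4,
                  sd_msa=0.5, sd_unit=0.7, sd_e=1.0):
    rows = []
    for m in range(n_msa):
        um = rng.normal(0, sd_msa)
        for c in range(per_msa):
            uc = rng.normal(0, sd_unit)
            x = rng.normal(size=days)
            y = beta * x + um + uc + rng.normal(0, sd_e, days)
            rows.append(pd.DataFrame({
                "y": y, "x": x, "msa": f"m{m}", "unit": f"m{m}c{c}",
                "date": np.arange(days), "w": rng.uniform(1, 3, days),
            }))
    return pd.concat(rows, ignore_index=True)


def _gls_oracle(panel, spec_vars):
    """Dense GLS at fixed variance components: independent of the Woodbury path."""
    y = panel["y"].to_numpy()
    X = np.column_stack([np.ones(len(panel)), panel["x"].to_numpy()])
    var_msa, var_unit, var_e = spec_vars
    V = np.zeros((len(panel), len(panel)))
    for col, v in (("msa", var_msa), ("unit", var_unit)):
        if col in panel:
            codes = pd.factorize(panel[col])[0]
            same = codes[:, None] == codes[None, :]
            V += v * same
    V += var_e * np.eye(len(panel))
    Vi = np.linalg.inv(V)
    return np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)


class TestFitMixed:
    def test_matches_statsmodels_unweighted_single_level(self, rng):
        panel = _one_level_panel(rng)
        for reml in (True, False):
            spec = ModelSpec("y", ["x"], [], group_msa=None, group_unit="unit",
                             weights=None, reml=reml)
            fit = fit_mixed(panel, spec)
            ref = MixedLM(panel["y"], sm.add_constant(panel["x"]),
                          groups=panel["unit"]).fit(reml=reml)
            assert np.allclose(fit.beta.values, np.asarray(ref.fe_params), atol=2e-6)
            assert fit.var_unit == pytest.approx(float(np.asarray(ref.cov_re)[0, 0]), abs=1e-4)
            assert fit.var_resid == pytest.approx(ref.scale, abs=1e-4)

    def test_matches_statsmodels_nested(self, rng):
        panel = _nested_panel(rng)
        spec = ModelSpec("y", ["x"], [], group_msa="msa", group_unit="unit",
                         weights=None, reml=True)
        fit = fit_mixed(panel, spec)
        ref = MixedLM.from_formula(
            "y ~ x", groups="msa", re_formula="1",
            vc_formula={"unit": "0 + C(unit)"}, data=panel,
        ).fit(reml=True)
        assert np.allclose(fit.beta.values, np.asarray(ref.fe_params), atol=1e-5)
        assert fit.var_unit == pytest.approx(float(ref.vcomp[0]), abs=1e-3)

    def test_agrees_with_dense_gls_oracle(self, rng):
        """At the fitted variance components, betas equal dense-matrix GLS."""
        panel = _one_level_panel(rng, n_groups=8, per=10)
        spec = ModelSpec("y", ["x"], [], group_msa=None, group_unit="unit",
                         weights=None, reml=True)
        fit = fit_mixed(panel, spec)
        oracle = _gls_oracle(panel.rename(columns={"unit": "unit"}),
                             (0.0, fit.var_unit, fit.var_resid))
        assert np.allclose(fit.beta.values, oracle, atol=1e-6)

    def test_weight_scaling_invariance(self, rng):
        panel = _nested_panel(rng)
        spec = ModelSpec("y", ["x"], [], group_msa="msa", group_unit="unit",
                         weights="w", reml=True)
        fit1 = fit_mixed(panel, spec)
        panel2 = panel.assign(w=panel["w"] * 37.5)
        fit2 = fit_mixed(panel2, spec)
        assert np.allclose(fit1.beta.values, fit2.beta.values, atol=1e-10)
        assert np.allclose(fit1.se.values, fit2.se.values, atol=1e-10)

    def test_row_permutation_invariance(self, rng):
        panel = _nested_panel(rng, n_msa=3, per_msa=3, days=40)
        spec = ModelSpec("y", ["x"], [], group_msa="msa", group_unit="unit",
                         weights="w", reml=True)
        fit1 = fit_mixed(panel, spec)
        fit2 = fit_mixed(panel.sample(frac=1.0, random_state=0), spec)
        assert np.allclose(fit1.beta.values, fit2.beta.values, atol=1e-9)
        assert fit1.var_unit == pytest.approx(fit2.var_unit, abs=1e-5)

    def test_zero_variance_generator_degenerates_to_wls(self, rng):
        panel = _nested_panel(rng, sd_msa=0.0, sd_unit=0.0, days=120)
        spec = ModelSpec("y", ["x"], [], group_msa="msa", group_unit="unit",
                         weights="w", reml=True)
        fit = fit_mixed(panel, spec)
        assert fit.var_msa < 0.02
        assert fit.var_unit < 0.02
        wls = sm.WLS(panel["y"], sm.add_constant(panel["x"]),
                     weights=panel["w"]).fit()
        assert np.allclose(fit.beta.values, np.asarray(wls.params), atol=5e-3)

    def test_rejects_single_group(self, rng):
        panel = _one_level_panel(rng, n_groups=1)
        spec = ModelSpec("y", ["x"], [], group_msa=None, group_unit="unit",
                         weights=None)
        with pytest.raises(ValueError, match="2 groups"):
            fit_mixed(panel, spec)

    def test_rank_deficient_design_names_columns(self, rng):
        panel = _one_level_panel(rng)
        panel["x2"] = panel["x"] * 2.0
        spec = ModelSpec("y", ["x", "x2"], [], group_msa=None,
                         group_unit="unit", weights=None)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_mixed(panel, spec)

    def test_serialization_round_trip(self, rng):
        panel = _nested_panel(rng, n_msa=3, per_msa=3, days=30)
        spec = ModelSpec("y", ["x"], [], group_msa="msa", group_unit="unit",
                         weights="w")
        fit = fit_mixed(panel, spec)
        back = MixedModelFit.from_dict(
            __import__("json").loads(__import__("json").dumps(fit.to_dict()))
        )
        assert np.allclose(back.beta.values, fit.beta.values)
        assert back.r2_conditional == pytest.approx(fit.r2_conditional)


class TestR2:
    def _fit(self, var_fixed, var_msa, var_unit, var_resid):
        idx = ["Intercept"]
        one = pd.Series([0.0], index=idx)
        return MixedModelFit(
            beta=one, se=one, pvalues=one,
            cov_fe=pd.DataFrame([[1.0]], index=idx, columns=idx),
            var_msa=var_msa, var_unit=var_unit, var_resid=var_resid,
            var_fixed=var_fixed, n_obs=10, n_groups={}, converged=True,
            method="REML", loglik=0.0,
        )

    def test_limits(self):
        assert conditional_r2(self._fit(1.0, 1.0, 0.0, 1e-12)) == pytest.approx(1.0)
        assert conditional_r2(self._fit(0.0, 0.0, 0.0, 2.0)) == 0.0

    def test_matches_independent_formula_and_ordering(self, rng):
        """Second implementation of the variance-partition formula."""
        for _ in range(25):
            vf, vm, vu, ve = rng.uniform(0.01, 2.0, 4)
            fit = self._fit(vf, vm, vu, ve)
            expected_cond = sum((vf, vm, vu)) / sum((vf, vm, vu, ve))
            expected_marg = vf / sum((vf, vm, vu, ve))
            assert conditional_r2(fit) == pytest.approx(expected_cond, abs=1e-12)
            assert marginal_r2(fit) == pytest.approx(expected_marg, abs=1e-12)
            assert marginal_r2(fit) <= conditional_r2(fit)

    def test_fitted_model_r2_bounds(self, rng):
        panel = _nested_panel(rng)
        spec = ModelSpec("y", ["x"], [], group_msa="msa", group_unit="unit",
                         weights="w")
        fit = fit_mixed(panel, spec)
        assert 0.0 <= fit.r2_marginal <= fit.r2_conditional <= 1.0


class TestResidualize:
    def _panel(self, rng, days=200):
        dates = pd.date_range("2013-01-01", periods=days, freq="D")
        dow = pd.get_dummies(dates.weekday).to_numpy()
        rows = []
        for c in range(3):
            eff = rng.normal(0, 1, 7)
            y = dow @ eff + rng.normal(0, 0.3, days)
            df = pd.DataFrame({"county_id": f"c{c}", "date": dates, "y": y, "w": 1.0})
            for i in range(7):
                df[f"dow_{i}"] = dow[:, i]
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def test_outcome_in_span_gives_zero_residuals(self, rng):
        panel = self._panel(rng)
        panel["y"] = 3.0 * panel["dow_2"] - 1.0
        res = residualize(panel, "y", [f"dow_{i}" for i in range(6)],
                          by="county_id", drop_reference=())
        assert np.allclose(res.values, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_nuisance(self, rng):
        panel = self._panel(rng)
        cols = [f"dow_{i}" for i in range(6)]
        res = residualize(panel, "y", cols, weights="w", by="county_id",
                          drop_reference=())
        for cty, sub in panel.groupby("county_id"):
            r = res.loc[sub.index]
            assert abs(r.mean()) < 1e-10
            for c in cols:
                x = sub[c].astype(float)
                assert abs(np.corrcoef(r, x - x.mean())[0, 1]) < 1e-8

    def test_orthogonal_outcome_residuals_are_centered_outcome(self, rng):
        days = 700
        dates = pd.date_range("2013-01-01", periods=days, freq="D")
        panel = pd.DataFrame({"county_id": "c", "date": dates})
        panel["dow_0"] = (dates.weekday == 0).astype(float)
        # outcome orthogonal to the nuisance column by construction
        y = rng.normal(size=days)
        x = panel["dow_0"] - panel["dow_0"].mean()
        y = y - (y @ x) / (x @ x) * x
        panel["y"] = y
        res = residualize(panel, "y", ["dow_0"], by=None, drop_reference=())
        assert np.allclose(res.values, y - y.mean(), atol=1e-10)


class TestIntercountyCorrelation:
    def test_identical_series(self, rng):
        x = rng.normal(size=100)
        wide = pd.DataFrame({"a": x, "b": x, "c": x})
        assert intercounty_correlation(wide) == pytest.approx(1.0)

    def test_negated_pair(self, rng):
        x = rng.normal(size=100)
        wide = pd.DataFrame({"a": x, "b": -x})
        assert intercounty_correlation(wide) == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        """Mean pairwise r over 9 white-noise counties stays below 0.05."""
        for seed in range(5):
            g = np.random.default_rng(seed)
            wide = pd.DataFrame(g.normal(size=(365, 9)),
                                columns=[f"c{i}" for i in range(9)])
            assert abs(intercounty_correlation(wide)) < 0.05

    def test_short_overlap_pair_skipped(self, rng):
        wide = pd.DataFrame({"a": rng.normal(size=10), "b": rng.normal(size=10),
                             "c": np.nan})
        wide.loc[0, "c"] = 1.0
        with pytest.warns(UserWarning, match="skipping pair"):
            r = intercounty_correlation(wide)
        assert np.isfinite(r)

    def test_long_format_accepted(self, rng):
        dates = pd.date_range("2013-01-01", periods=50, freq="D")
        x = rng.normal(size=50)
        long = pd.concat([
            pd.DataFrame({"county_id": "a", "date": dates, "resid": x}),
            pd.DataFrame({"county_id": "b", "date": dates, "resid": x}),
        ])
        assert intercounty_correlation(long) == pytest.approx(1.0)
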