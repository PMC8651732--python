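import json
import subprocess

import numpy as np
import pandas as pd
import pytest

import plastevol as pe
from plastevol.exceptions import (
    ConvergenceError,
    RankDeficiencyError,
    SingleLevelFactorError,
)
from plastevol.mixedmodel import ModelSpec, compute_r2_from_components

from conftest import make_grouped_data


class TestFitLmm:
    def test_noise_free_exact_recovery(self, rng):
        df = make_grouped_data(rng, slope=3.0, group_effect=-1.5,
                               sigma_group=0.0, sigma_resid=0.0)
        fit = pe.fit_lmm(df, ModelSpec("y", ("x", "c"), random_intercepts=("g",)))
        assert fit.degenerate
        assert fit.coefficients["x"] == pytest.approx(3.0, abs=1e-8)
        assert fit.coefficients["c"] == pytest.approx(-1.5, abs=1e-8)
        assert fit.var_residual == 0.0

    def test_matches_ols_when_no_group_variance(self, rng):
        # identical within-group covariate pattern in every group makes the
        # GLS and OLS estimators coincide exactly, whatever the variance fit
        n_groups, per = 20, 15
        x_pattern = rng.normal(size=per)
        g = np.repeat(np.arange(n_groups), per)
        x = np.tile(x_pattern, n_groups)
        y = 0.5 + 2.0 * x + rng.normal(0, 1.0, n_groups * per)
        df = pd.DataFrame(dict(y=y, x=x, g=g))
        fit = pe.fit_lmm(df, ModelSpec("y", ("x",), random_intercepts=("g",)))
        X = np.column_stack([np.ones(len(df)), x])
        beta_ols = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.coefficients["Intercept"] == pytest.approx(beta_ols[0], abs=1e-6)
        assert fit.coefficients["x"] == pytest.approx(beta_ols[1], abs=1e-6)

    def test_balanced_two_group_difference(self, rng):
        df = make_grouped_data(rng, n_groups=10, per_group=12, slope=0.0,
                               group_effect=2.5, sigma_group=0.0, sigma_resid=1.0)
        df = df.drop(columns="x")
        fit = pe.fit_lmm(df, ModelSpec("y", ("c",), random_intercepts=("g",)))
        means = df.groupby("c")["y"].mean()
        assert fit.coefficients["c"] == pytest.approx(means[1.0] - means[0.0], abs=1e-6)

    def test_rank_deficiency_names_aliased_terms(self, rng):
        df = make_grouped_data(rng)
        df["x2"] = 2.0 * df["x"]
        with pytest.raises(RankDeficiencyError) as err:
            pe.fit_lmm(df, ModelSpec("y", ("x", "x2"), random_intercepts=("g",)))
        assert "x2" in err.value.aliased or "x" in err.value.aliased

    def test_single_level_random_factor_rejected(self, rng):
        df = make_grouped_data(rng)
        df["g"] = "only"
        with pytest.raises(SingleLevelFactorError):
            pe.fit_lmm(df, ModelSpec("y", ("x",), random_intercepts=("g",)))

    def test_missing_values_rejected(self, rng):
        df = make_grouped_data(rng)
        df.loc[3, "x"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            pe.fit_lmm(df, ModelSpec("y", ("x",), random_intercepts=("g",)))

    def test_interaction_terms_validated(self):
        with pytest.raises(ValueError, match="absent"):
            ModelSpec("y", ("x",), interactions=(("x", "z"),))


@pytest.fixture(scope="module")
def fixture_fits(tmp_path_factory):
    rng = np.random.default_rng(99)
    df = make_grouped_data(rng, n_groups=14, per_group=9, slope=0.8,
                           group_effect=0.5, sigma_group=1.2, sigma_resid=1.0)
    h = np.tile(np.arange(6), len(df) // 6)
    df["h"] = [f"h{i}" for i in h]
    df["y2"] = df["y"] + np.random.default_rng(5).normal(0, 0.9, 6)[h]
    path = tmp_path_factory.mktemp("r") / "fixture.csv"
    df.to_csv(path, index=False)
    rscript = f"""
    suppressMessages(library(lmerTest)); suppressMessages(library(jsonlite))
    d <- read.csv("{path}")
    m1 <- lmer(y ~ x + c + (1|g), data=d, REML=TRUE)
    m2 <- lmer(y2 ~ x + c + (1|g) + (1|h), data=d, REML=TRUE)
    s1 <- summary(m1)$coefficients; s2 <- summary(m2)$coefficients
    out <- list(
      m1=list(est=s1[,1], se=s1[,2], df=s1[,3], p=s1[,5],
              vc=as.data.frame(VarCorr(m1))$vcov),
      m2=list(est=s2[,1], se=s2[,2], df=s2[,3], p=s2[,5],
              vc=as.data.frame(VarCorr(m2))$vcov))
    cat(toJSON(out, digits=10))
    """
    ref = json.loads(
        subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                       text=True, check=True).stdout
    )
    fit1 = pe.fit_lmm(df, ModelSpec("y", ("x", "c"), random_intercepts=("g",)))
    fit2 = pe.fit_lmm(df, ModelSpec("y2", ("x", "c"), random_intercepts=("g", "h")))
    return ref, fit1, fit2


class TestAgainstLmerTest:
    """Independent oracle: R lmerTest/lme4 on the same data."""

    def test_single_factor_matches(self, fixture_fits):
        ref, fit, _ = fixture_fits
        est = [fit.coefficients[t] for t in fit.terms]
        se = [fit.standard_errors[t] for t in fit.terms]
        dfs = [fit.dof[t] for t in fit.terms]
        p = [fit.p_values[t] for t in fit.terms]
        assert np.allclose(est, ref["m1"]["est"], rtol=1e-5)
        assert np.allclose(se, ref["m1"]["se"], rtol=1e-4)
        assert np.allclose(dfs, ref["m1"]["df"], rtol=1e-2)
        assert np.allclose(p, ref["m1"]["p"], rtol=0.02, atol=1e-6)
        assert fit.var_random["g"] == pytest.approx(ref["m1"]["vc"][0], rel=1e-4)
        assert fit.var_residual == pytest.approx(ref["m1"]["vc"][1], rel=1e-4)

    def test_crossed_factors_match(self, fixture_fits):
        ref, _, fit = fixture_fits
        est = [fit.coefficients[t] for t in fit.terms]
        se = [fit.standard_errors[t] for t in fit.terms]
        dfs = [fit.dof[t] for t in fit.terms]
        assert np.allclose(est, ref["m2"]["est"], rtol=1e-4, atol=1e-6)
        assert np.allclose(se, ref["m2"]["se"], rtol=1e-3)
        assert np.allclose(dfs, ref["m2"]["df"], rtol=0.05)
        # lme4 orders VarCorr components g, h (grouping factors by levels)
        mine = sorted(fit.var_random.values()) + [fit.var_residual]
        theirs = sorted(ref["m2"]["vc"][:2]) + [ref["m2"]["vc"][2]]
        assert np.allclose(mine, theirs, rtol=5e-3, atol=1e-6)


class TestR2:
    def test_printed_formula_values(self):
        r2 = compute_r2_from_components(2.0, 1.0, 1.0)
        assert r2.r2_marginal == pytest.approx(0.5)
        assert r2.r2_conditional == pytest.approx(0.75)

    def test_marginal_equals_conditional_without_random(self):
        r2 = compute_r2_from_components(3.0, 0.0, 2.0)
        assert r2.r2_marginal == r2.r2_conditional

    def test_zero_fixed_variance(self):
        assert compute_r2_from_components(0.0, 1.0, 1.0).r2_marginal == 0.0

    def test_random_triples_ordering(self, rng):
        for _ in range(20):
            vf, vr, ve = rng.uniform(0.0, 5.0, 3)
            ve = max(ve, 1e-3)
            r2 = compute_r2_from_components(vf, vr, ve)
            assert 0.0 <= r2.r2_marginal <= r2.r2_conditional <= 1.0
            assert r2.r2_marginal == pytest.approx(vf / (vf + vr + ve))
            assert r2.r2_conditional == pytest.approx((vf + vr) / (vf + vr + ve))

    def test_zero_total_variance_rejected(self):
        with pytest.raises(ValueError):
            compute_r2_from_components(0.0, 0.0, 0.0)

    def test_from_fit_sigma_f_definition(self, rng):
        """sigma_f^2 is the (n-1)-denominator variance of the fixed-effect
        linear predictor, checked by hand on a tiny design."""
        df = make_grouped_data(rng, n_groups=3, per_group=2, sigma_group=0.5)
        fit = pe.fit_lmm(df, ModelSpec("y", ("x", "c"), random_intercepts=("g",)))
        pred = (fit.coefficients["Intercept"]
                + fit.coefficients["x"] * df["x"].to_numpy()
                + fit.coefficients["c"] * df["c"].to_numpy())
        assert fit.var_fixed == pytest.approx(np.var(pred, ddof=1))
        r2 = pe.compute_r2(fit)
        assert 0 <= r2.r2_marginal <= r2.r2_conditional <= 1


class TestDiagnostics:
    def test_noise_free_zeros(self, rng):
        df = make_grouped_data(rng, sigma_group=0.0, sigma_resid=0.0)
        fit = pe.fit_lmm(df, ModelSpec("y", ("x", "c"), random_intercepts=("g",)))
        diag = pe.diagnostics(fit)
        assert np.allclose(diag.residuals, 0.0, atol=1e-8)
        assert np.allclose(diag.influence, 0.0, atol=1e-8)

    def test_outlier_has_max_influence_vs_brute_force(self, rng):
        df = make_grouped_data(rng, n_groups=6, per_group=5, sigma_group=0.0,
                               sigma_resid=0.5).drop(columns="g")
        df.loc[7, "y"] += 25.0
        spec = ModelSpec("y", ("x", "c"))
        fit = pe.fit_lmm(df, spec)
        diag = pe.diagnostics(fit)
        assert int(np.argmax(diag.influence)) == 7
        # brute-force leave-one-out refits agree on the ranking
        base = fit.coef_array
        disps = []
        for i in range(len(df)):
            f_i = pe.fit_lmm(df.drop(index=i).reset_index(drop=True), spec)
            disps.append(np.linalg.norm(f_i.coef_array - base))
        assert int(np.argmax(disps)) == 7

    def test_qq_near_identity_for_gaussian(self, rng):
        df = make_grouped_data(rng, n_groups=20, per_group=50, sigma_group=0.3,
                               sigma_resid=1.0)
        fit = pe.fit_lmm(df, ModelSpec("y", ("x", "c"), random_intercepts=("g",)))
        diag = pe.diagnostics(fit)
        r = np.corrcoef(diag.qq_theoretical, diag.qq_sample)[0, 1]
        assert r > 0.99
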